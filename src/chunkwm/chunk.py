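"""Posterior chunking layer: merges sensory input with nearby PFC content.

A ring-attractor layer (one unit per preferred color, matching the color
layers) receives convergent excitation from the bottom-up sensory bump
and topographic top-down projections from every PFC maintenance stripe.
Bottom-up input is deliberately stronger than top-down (more synapses /
proximity to the soma, expressed as a relative projection scale), so the
settled activity mirrors the sensory input unless a maintained PFC bump
overlaps it, in which case the convergent excitation pulls the settled
bump toward that nearest neighbor -- a candidate "chunk".  Pooled
lateral inhibition suppresses the influence of distant PFC bumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import InhibParams, Layer, Projection, UnitParams, settle
from .popcode import PopulationBump, decode_color, encode_color

__all__ = [
    "ChunkLayerSpec",
    "chunk_settle",
    "chunk_settle_layers",
    "chunking_profile",
]


@dataclass(frozen=True)
class ChunkLayerSpec:
    """Wiring constants of the chunk layer.

    ``input_scale`` / ``pfc_scale`` set the relative strengths of the
    bottom-up sensory projection and each top-down deep-PFC projection;
    bottom-up must dominate (input_scale > pfc_scale) so that chunking
    is a bias, not a takeover.  The 2:1 default ratio together with the
    inhibition gain places the peak of the attraction profile at an
    intermediate (20-60 degree) offset.
    """

    n_units: int = 20
    n_pfc_slots: int = 2            # top-down projections (one per stripe)
    input_scale: float = 2.0
    pfc_scale: float = 1.0
    inhib: InhibParams = field(
        default_factory=lambda: InhibParams(Gi=2.0, ff_floor=0.05)
    )
    unit: UnitParams = field(default_factory=UnitParams)
    n_cycles: int = 40

    def __post_init__(self) -> None:
        if not (self.input_scale > self.pfc_scale > 0):
            raise ValueError("require input_scale > pfc_scale > 0")


def chunk_settle(
    sensory: PopulationBump,
    pfc_maintained: list[PopulationBump],
    spec: ChunkLayerSpec | None = None,
) -> PopulationBump:
    """Settle the chunk layer given sensory input and maintained PFC bumps.

    All ``n_pfc_slots`` top-down projections always participate in the
    net-input normalization; slots beyond the provided list (empty
    stripes) simply contribute zero activity.  Returns the settled
    chunk-layer activity as a bump over the same preferred colors.
    """
    spec = spec or ChunkLayerSpec()
    n = spec.n_units
    if sensory.n_units != n:
        raise ValueError("sensory bump size must match chunk layer size")
    if len(pfc_maintained) > spec.n_pfc_slots:
        raise ValueError("more PFC bumps than top-down slots")

    # All senders are clamped within the trial phase, so the net input
    # is constant across settling cycles; only the inhibition pool and
    # the rate code need iterating.  (settle() over explicit Layer
    # objects gives the identical fixed point, since the rate code
    # depends only on (ge, gi); see the equivalence test.)
    total_rel = spec.input_scale + spec.n_pfc_slots * spec.pfc_scale
    ge = (spec.input_scale / total_rel) * sensory.activities
    for k in range(spec.n_pfc_slots):
        if k < len(pfc_maintained):
            ge = ge + (spec.pfc_scale / total_rel) \
                * pfc_maintained[k].activities
    # inlined FFFB + rate-code iteration (identical arithmetic to
    # fffb_inhibition / activation, without per-cycle call overhead)
    u, ih = spec.unit, spec.inhib
    inv_n = 1.0 / n
    ff = ih.ff_gain * max(float(np.add.reduce(ge)) * inv_n - ih.ff_floor, 0.0)
    ge_th_slope = u.gbar_i * (u.E_i - u.Theta) / (u.Theta - u.E_e)
    ge_th_leak = u.gbar_l * (u.E_l - u.Theta) / (u.Theta - u.E_e)
    y = np.zeros(n)
    fb = 0.0
    for cyc in range(spec.n_cycles):
        fb += ih.fb_dt * (ih.fb_gain * float(np.add.reduce(y)) * inv_n - fb)
        gi = ih.Gi * (ff + fb)
        z = np.maximum(ge - (gi * ge_th_slope + ge_th_leak), 0.0)
        gz = u.gamma * z
        dy = 0.5 * (gz / (1.0 + gz) - y)
        y = y + dy
        if cyc % 4 == 3 and float(np.max(np.abs(dy))) < 1e-4:
            break
    return PopulationBump(y, sensory.preferred)


def chunk_settle_layers(
    sensory: PopulationBump,
    pfc_maintained: list[PopulationBump],
    spec: ChunkLayerSpec | None = None,
) -> PopulationBump:
    """Reference implementation of :func:`chunk_settle` via explicit
    layers and the generic settling loop (used for cross-checking)."""
    spec = spec or ChunkLayerSpec()
    n = spec.n_units
    sens = Layer("sensory", n, params=spec.unit)
    sens.clamp(sensory.activities)
    layers = [sens]
    pairs: list[tuple[Layer, Projection]] = [
        (sens, Projection.one_to_one(n, rel_scale=spec.input_scale))
    ]
    for k in range(spec.n_pfc_slots):
        ly = Layer(f"pfc{k}", n, params=spec.unit)
        act = (
            pfc_maintained[k].activities
            if k < len(pfc_maintained)
            else np.zeros(n)
        )
        ly.clamp(act)
        layers.append(ly)
        pairs.append((ly, Projection.one_to_one(n, rel_scale=spec.pfc_scale)))

    chunk = Layer("chunk", n, params=spec.unit, inhib=spec.inhib)
    layers.append(chunk)
    result = settle(layers, {"chunk": pairs}, n_cycles=spec.n_cycles)
    return PopulationBump(result.activities["chunk"], sensory.preferred)


def chunking_profile(
    delta_grid: np.ndarray,
    spec: ChunkLayerSpec | None = None,
    theta: float = np.pi,
) -> np.ndarray:
    """Deviation of the decoded chunk from the sensory value vs PFC offset.

    For each angular offset in ``delta_grid`` (radians, signed), one PFC
    bump is placed at ``theta + offset`` and the chunk layer is settled;
    the returned curve gives the signed angular deviation (degrees) of
    the decoded chunk representation from the sensory value.  The curve
    rises from 0, peaks at an intermediate offset and returns toward 0
    at large offsets, where lateral inhibition leaves the layer
    mirroring the input.
    """
    spec = spec or ChunkLayerSpec()
    sens = encode_color(theta, n_units=spec.n_units)
    out = np.empty(len(delta_grid))
    for i, d in enumerate(np.asarray(delta_grid, dtype=float)):
        pfc = encode_color(theta + d, n_units=spec.n_units)
        merged = chunk_settle(sens, [pfc], spec)
        dec, r = decode_color(merged.activities, merged.preferred)
        if r == 0 or not np.isfinite(dec):
            out[i] = np.nan
        else:
            out[i] = np.degrees(np.angle(np.exp(1j * (dec - theta))))
    return out
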