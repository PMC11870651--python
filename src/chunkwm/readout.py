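"""Error-driven learning of the response pathways.

Two plastic mappings drive the output (color report) layer: the direct
input -> output map, exercised on every store/ignore trial (the model
must report the currently presented color), and the PFC-output ->
output map, exercised on recall trials when maintained content is
output-gated.  Both learn from the discrepancy between the settled
output activity and the output layer clamped to the target color bump
(a two-phase contrastive delta rule); all other projections in the
circuit are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import InhibParams, UnitParams
from .popcode import PopulationBump, decode_color, encode_color

__all__ = ["OutputMapping", "output_activity", "train_step_output"]


@dataclass
class OutputMapping:
    """Plastic response-pathway weights and the output layer's constants."""

    n_in: int = 20
    n_out: int = 20
    lrate: float = 0.2
    unit: UnitParams = field(default_factory=UnitParams)
    inhib: InhibParams = field(
        default_factory=lambda: InhibParams(Gi=1.0, ff_floor=0.02)
    )
    n_cycles: int = 30
    w_direct: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_pfc_out: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.w_direct is None:
            self.w_direct = np.zeros((self.n_in, self.n_out))
        if self.w_pfc_out is None:
            self.w_pfc_out = np.zeros((self.n_in, self.n_out))

    @classmethod
    def random_init(
        cls, rng: np.random.Generator, scale: float = 0.05, **kwargs
    ) -> "OutputMapping":
        m = cls(**kwargs)
        m.w_direct = rng.uniform(0.0, scale, size=m.w_direct.shape)
        m.w_pfc_out = rng.uniform(0.0, scale, size=m.w_pfc_out.shape)
        return m


def _settle_output(
    mapping: OutputMapping,
    pre_direct: np.ndarray | None,
    pre_pfc: np.ndarray | None,
) -> np.ndarray:
    """Settle the output layer under drive from the two response paths.

    Both projections always participate in the net-input normalization
    (a silent path contributes zero activity), mirroring the fixed
    netin scaling used elsewhere.  Because the rate code depends only on
    (ge, gi) and the senders are static within a trial phase, the
    settling loop iterates only the inhibition pool and activation.
    """
    n = mapping.n_out
    ge = np.zeros(n)
    if pre_direct is not None:
        ge = ge + (pre_direct @ mapping.w_direct) / mapping.n_in
    if pre_pfc is not None:
        ge = ge + (pre_pfc @ mapping.w_pfc_out) / mapping.n_in
    ge = ge / 2.0  # rel-scale-weighted average over the two paths
    # inlined FFFB + rate-code iteration (same arithmetic as
    # fffb_inhibition / activation; senders are static per phase)
    u, ih = mapping.unit, mapping.inhib
    inv_n = 1.0 / n
    ff = ih.ff_gain * max(float(np.add.reduce(ge)) * inv_n - ih.ff_floor, 0.0)
    ge_th_slope = u.gbar_i * (u.E_i - u.Theta) / (u.Theta - u.E_e)
    ge_th_leak = u.gbar_l * (u.E_l - u.Theta) / (u.Theta - u.E_e)
    y = np.zeros(n)
    fb = 0.0
    for cyc in range(mapping.n_cycles):
        fb += ih.fb_dt * (ih.fb_gain * float(np.add.reduce(y)) * inv_n - fb)
        gi = ih.Gi * (ff + fb)
        z = np.maximum(ge - (gi * ge_th_slope + ge_th_leak), 0.0)
        gz = u.gamma * z
        dy = 0.5 * (gz / (1.0 + gz) - y)
        y = y + dy
        # convergence checked sparsely; the fb average converges
        # geometrically so most of the cost is early cycles anyway
        if cyc % 4 == 3 and float(np.max(np.abs(dy))) < 1e-4:
            break
    return y


def output_activity(
    mapping: OutputMapping,
    pre_direct: np.ndarray | None = None,
    pre_pfc: np.ndarray | None = None,
) -> PopulationBump:
    """Settled output-layer activity for the given pathway drives."""
    return PopulationBump(_settle_output(mapping, pre_direct, pre_pfc))


def _soft_bounded_update(w: np.ndarray, dw: np.ndarray) -> np.ndarray:
    """Soft weight bounding: LTP scales with (1 - w), LTD with w.

    Keeps weights in [0, 1] with an equilibrium in the interior, so
    uncorrelated pre/target episodes (e.g. early recalls that read out
    the wrong stripe) cannot ratchet the whole matrix to the ceiling.
    """
    return w + np.where(dw > 0, dw * (1.0 - w), dw * w)


def train_step_output(
    current_drive: tuple[np.ndarray | None, np.ndarray | None],
    target_color: float,
    mapping: OutputMapping,
    settled: np.ndarray | None = None,
    target_act: np.ndarray | None = None,
) -> float:
    """One error-driven update of the active response mapping(s).

    ``current_drive`` is ``(pre_direct, pre_pfc)`` presynaptic activity;
    a ``None`` entry leaves that pathway's weights untouched (no
    presynaptic activity, no plasticity).  The output layer is settled
    (expectation phase), then compared against the layer clamped to the
    encoded target color (outcome phase); weights move along the
    presynaptic x error outer product, clipped to [0, 1].  Returns the
    absolute decode error (degrees) of the expectation-phase output.

    ``settled`` and ``target_act`` allow a caller that has already
    settled the output layer (or already encoded the target) to skip
    the redundant computation.
    """
    pre_direct, pre_pfc = current_drive
    y = (
        settled
        if settled is not None
        else _settle_output(mapping, pre_direct, pre_pfc)
    )
    if target_act is None:
        target_act = encode_color(
            target_color, n_units=mapping.n_out
        ).activities
    err_vec = target_act - y
    if pre_direct is not None and np.any(pre_direct):
        mapping.w_direct = _soft_bounded_update(
            mapping.w_direct, mapping.lrate * np.outer(pre_direct, err_vec)
        )
    if pre_pfc is not None and np.any(pre_pfc):
        mapping.w_pfc_out = _soft_bounded_update(
            mapping.w_pfc_out, mapping.lrate * np.outer(pre_pfc, err_vec)
        )
    dec, r = decode_color(y)
    if not np.isfinite(dec) or r == 0.0:
        return 180.0
    from .popcode import circular_error

    return abs(circular_error(dec, target_color))
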