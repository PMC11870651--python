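"""Rate-coded point-neuron dynamics with pooled FFFB lateral inhibition.

Every layer in the circuit is built from the same primitives:

* a point neuron whose membrane potential integrates excitatory,
  inhibitory and leak currents toward a conductance-weighted equilibrium,
* a thresholded rate-code activation computed from the excess of
  excitatory conductance over the amount that would hold the equilibrium
  potential exactly at the firing threshold,
* a single inhibitory pool per layer combining feedforward inhibition
  (driven by the layer's mean net input) and feedback inhibition (driven
  by its mean firing rate).

Potentials are on a normalized 0-1 scale; conductances are dimensionless
channel-open fractions multiplied by maximal conductances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UnitParams",
    "UnitState",
    "InhibParams",
    "Projection",
    "Layer",
    "net_excitation",
    "step_membrane",
    "g_e_theta",
    "activation",
    "fffb_inhibition",
    "settle",
    "SettleResult",
]


@dataclass(frozen=True)
class UnitParams:
    """Biophysical constants of a rate-coded point neuron.

    Defaults follow standard published Leabra values on the normalized
    potential scale: E_i <= E_l < Theta < E_e, leak channel always open
    with a small maximal conductance.
    """

    Cm: float = 1.0          # membrane capacitance (sets the time constant)
    E_e: float = 1.0         # excitatory reversal potential
    E_i: float = 0.25        # inhibitory reversal potential
    E_l: float = 0.3         # leak reversal potential
    gbar_e: float = 1.0      # maximal conductances
    gbar_i: float = 1.0
    gbar_l: float = 0.1
    Theta: float = 0.5       # firing threshold potential
    gamma: float = 100.0     # activation gain

    def __post_init__(self) -> None:
        if not (self.E_i <= self.E_l < self.Theta < self.E_e):
            raise ValueError("require E_i <= E_l < Theta < E_e")
        if min(self.gbar_e, self.gbar_i, self.gbar_l) < 0:
            raise ValueError("maximal conductances must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class UnitState:
    """Dynamic variables of one unit (or a whole layer, vectorized)."""

    Vm: np.ndarray
    ge: np.ndarray
    gi: np.ndarray
    y: np.ndarray

    @classmethod
    def zeros(cls, n: int, params: UnitParams | None = None) -> "UnitState":
        p = params or UnitParams()
        return cls(
            Vm=np.full(n, p.E_l),
            ge=np.zeros(n),
            gi=np.zeros(n),
            y=np.zeros(n),
        )


@dataclass(frozen=True)
class InhibParams:
    """FFFB pooled-inhibition constants for one layer."""

    Gi: float = 1.8          # overall inhibitory gain (layer sparsity)
    ff_gain: float = 1.0     # feedforward coefficient on mean net input
    fb_gain: float = 1.0     # feedback coefficient on mean activation
    ff_floor: float = 0.1    # net-input floor below which ff contributes 0
    fb_dt: float = 0.7       # single-cycle exponential-average rate for fb

    def __post_init__(self) -> None:
        if min(self.Gi, self.ff_gain, self.fb_gain, self.ff_floor) < 0:
            raise ValueError("InhibParams must all be >= 0")
        if not 0 < self.fb_dt <= 1:
            raise ValueError("fb_dt must be in (0, 1]")


@dataclass
class Projection:
    """Weighted connection from a sending layer to a receiving layer.

    ``weights`` has shape (n_send, n_recv) with entries in [0, 1].  An
    optional boolean ``mask`` of the same shape marks which connections
    structurally exist; the per-receiver fan-in used to normalize the net
    input is the count of existing connections, so a one-to-one
    topographic projection passes its sender through at full strength.
    """

    weights: np.ndarray
    rel_scale: float = 1.0
    plastic: bool = False
    mask: np.ndarray | None = None
    fan_in: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        if self.rel_scale <= 0:
            raise ValueError("rel_scale must be > 0")
        if self.mask is None:
            fan = np.full(self.weights.shape[1], float(self.weights.shape[0]))
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.weights.shape:
                raise ValueError("mask shape must match weights")
            fan = self.mask.sum(axis=0).astype(float)
        self.fan_in = np.maximum(fan, 1.0)

    @classmethod
    def one_to_one(cls, n: int, weight: float = 1.0, rel_scale: float = 1.0,
                   plastic: bool = False) -> "Projection":
        eye = np.eye(n, dtype=bool)
        return cls(weights=np.eye(n) * weight, rel_scale=rel_scale,
                   plastic=plastic, mask=eye)


def net_excitation(
    sender_activities: list[np.ndarray] | np.ndarray,
    projections: list[Projection] | Projection,
) -> np.ndarray:
    """Excitatory conductance per receiving unit from converging projections.

    Each projection contributes the fan-in-normalized mean of
    ``x_i * w_i`` over its existing connections; contributions are
    combined as a rel_scale-weighted average across all projections
    passed in (projections from currently silent layers still count in
    the normalization, so a layer's drive does not inflate when one of
    its sources goes quiet).
    """
    if isinstance(projections, Projection):
        projections = [projections]
        sender_activities = [np.asarray(sender_activities)]
    if not projections:
        raise ValueError("need at least one projection")
    if len(sender_activities) != len(projections):
        raise ValueError("one sender activity vector per projection")
    total_rel = sum(p.rel_scale for p in projections)
    ge = None
    for x, p in zip(sender_activities, projections):
        x = np.asarray(x, dtype=float)
        if x.shape[0] != p.weights.shape[0]:
            raise ValueError(
                f"sender activity length {x.shape[0]} does not match "
                f"projection with {p.weights.shape[0]} senders"
            )
        w = p.weights if p.mask is None else p.weights * p.mask
        contrib = (x @ w) / p.fan_in
        term = (p.rel_scale / total_rel) * contrib
        ge = term if ge is None else ge + term
    return ge


def step_membrane(
    state: UnitState, params: UnitParams, dt: float = 0.15
) -> UnitState:
    """One explicit-Euler step of the membrane equation.

    With constant conductances the update moves Vm monotonically toward
    the conductance-weighted mean of the reversal potentials.  The
    per-step integration rate is clamped at 1 so Vm always remains a
    convex combination of its old value and the equilibrium, keeping it
    inside the reversal-potential bounds for any inputs.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ge = np.clip(state.ge, 0.0, None) * params.gbar_e
    gi = np.clip(state.gi, 0.0, None) * params.gbar_i
    gl = params.gbar_l  # leak channel fraction is always 1
    g_tot = ge + gi + gl
    with np.errstate(invalid="ignore", divide="ignore"):
        v_eq = np.where(
            g_tot > 0,
            (ge * params.E_e + gi * params.E_i + gl * params.E_l)
            / np.where(g_tot > 0, g_tot, 1.0),
            state.Vm,
        )
    rate = np.minimum(dt / params.Cm * g_tot, 1.0)
    Vm = state.Vm + rate * (v_eq - state.Vm)
    return replace(state, Vm=Vm)


def g_e_theta(gi: np.ndarray | float, params: UnitParams) -> np.ndarray | float:
    """Excitatory conductance putting the equilibrium potential at threshold.

    Depends on the current inhibition and leak:
    geTheta = [gbar_i*gi*(E_i - Theta) + gbar_l*(E_l - Theta)] / (Theta - E_e).
    """
    num = (
        params.gbar_i * np.asarray(gi, dtype=float) * (params.E_i - params.Theta)
        + params.gbar_l * (params.E_l - params.Theta)
    )
    return num / (params.Theta - params.E_e)


def activation(
    ge: np.ndarray | float, gi: np.ndarray | float, params: UnitParams
) -> np.ndarray | float:
    """Thresholded sigmoidal rate code y = 1 / (1 + 1/(gamma*[ge - geTheta]+)).

    Zero at or below the threshold conductance, saturating toward 1 for
    large excitation; nondecreasing in ge and nonincreasing in gi.
    """
    z = np.maximum(np.asarray(ge, dtype=float) - g_e_theta(gi, params), 0.0)
    gz = params.gamma * z
    y = gz / (1.0 + gz)
    if np.ndim(ge) == 0 and np.ndim(gi) == 0:
        return float(y)
    return y


def fffb_inhibition(
    layer_net_input: np.ndarray,
    layer_activity: np.ndarray,
    params: InhibParams,
    fb_prev: float | None = None,
) -> tuple[float, float]:
    """Pooled FFFB inhibitory conductance for one layer.

    gi = Gi * (ff + fb) with ff = ff_gain * [mean net input - ff_floor]+
    and fb a single-cycle exponential average of fb_gain * mean activity
    (the averaging prevents inhibitory oscillation in small layers).
    Returns ``(gi, fb)`` so callers can carry the fb average across
    settling cycles; pass ``fb_prev=None`` for a stateless evaluation.
    """
    netin = np.asarray(layer_net_input, dtype=float)
    act = np.asarray(layer_activity, dtype=float)
    if netin.min(initial=0.0) < 0 or act.min(initial=0.0) < 0:
        raise ValueError("net input and activity must be >= 0")
    ff = params.ff_gain * max(float(netin.mean()) - params.ff_floor, 0.0)
    fb_target = params.fb_gain * float(act.mean())
    if fb_prev is None:
        fb = fb_target
    else:
        fb = fb_prev + params.fb_dt * (fb_target - fb_prev)
    return params.Gi * (ff + fb), fb


@dataclass
class Layer:
    """A named layer: unit parameters, inhibition pool, and dynamic state."""

    name: str
    n: int
    params: UnitParams = field(default_factory=UnitParams)
    inhib: InhibParams = field(default_factory=InhibParams)
    clamped: bool = False

    def __post_init__(self) -> None:
        self.state = UnitState.zeros(self.n, self.params)
        self.fb = 0.0

    def reset(self) -> None:
        self.state = UnitState.zeros(self.n, self.params)
        self.fb = 0.0

    def clamp(self, activities: np.ndarray) -> None:
        self.state.y = np.asarray(activities, dtype=float).copy()
        self.clamped = True


@dataclass(frozen=True)
class SettleResult:
    activities: dict[str, np.ndarray]
    cycles: int
    converged: bool


def settle(
    layers: list[Layer],
    incoming: dict[str, list[tuple[Layer, Projection]]],
    n_cycles: int = 50,
    dt: float = 0.15,
    tol: float = 1e-4,
    act_dt: float = 0.5,
) -> SettleResult:
    """Iterate net input -> FFFB -> membrane -> activation to a fixed point.

    ``incoming`` maps a receiving layer name to its (sender layer,
    projection) pairs.  Clamped layers hold their activities fixed and
    only send.  Stops early once the largest activity change over a
    cycle falls below ``tol``; raises on non-finite activity, naming the
    offending layer.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    free = [ly for ly in layers if not ly.clamped]
    cycles_run = 0
    converged = False
    for cyc in range(n_cycles):
        cycles_run = cyc + 1
        max_delta = 0.0
        for ly in free:
            pairs = incoming.get(ly.name, [])
            if pairs:
                senders = [p[0].state.y for p in pairs]
                projs = [p[1] for p in pairs]
                ge = net_excitation(senders, projs)
            else:
                ge = np.zeros(ly.n)
            gi, ly.fb = fffb_inhibition(ge, ly.state.y, ly.inhib, ly.fb)
            ly.state.ge = ge
            ly.state.gi = np.full(ly.n, gi)
            ly.state = step_membrane(ly.state, ly.params, dt)
            y_new = activation(ge, gi, ly.params)
            delta = act_dt * (y_new - ly.state.y)
            ly.state.y = ly.state.y + delta
            if not np.all(np.isfinite(ly.state.y)):
                raise FloatingPointError(
                    f"non-finite activity in layer {ly.name!r}"
                )
            if delta.size:
                max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < tol:
            converged = True
            break
    return SettleResult(
        activities={ly.name: ly.state.y.copy() for ly in layers},
        cycles=cycles_run,
        converged=converged,
    )
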