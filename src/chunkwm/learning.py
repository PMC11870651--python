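"""Reward, dopamine, and corticostriatal plasticity.

Learning of gating policies is driven by a single scalar reward per
recall trial.  A Rescorla-Wagner critic tracks expected reward; the
difference (reward prediction error, RPE) is conveyed as a dopamine
burst (positive) or dip (negative), each with its own gain.  Gating
events leave eligibility tags on the corticostriatal synapses that
drove them ("synaptic tagging"); at reward time the effective RPE
multiplies these tags to strengthen Go weights and weaken NoGo weights
(or the reverse for dips), implementing opponent Go/NoGo learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popcode import circular_error

__all__ = [
    "Critic",
    "DAParams",
    "SynapticTags",
    "compute_reward",
    "da_modulate",
    "update_striatal",
    "gating_policy_metric",
]

#: Absolute error (degrees) at which the linear reward crosses zero;
#: closer reports earn positive reward, farther ones negative.
REWARD_ZERO_ERROR_DEG = 45.0


@dataclass
class Critic:
    """Running estimate of expected reward (Rescorla-Wagner delta rule).

    V starts at the reward floor (pessimistic initialization), so early
    outcomes arrive as positive prediction errors; this sustains
    exploration of gating strategies while the response pathway is
    still untrained, instead of indiscriminately punishing every early
    gating event.
    """

    V: float = -1.0
    alpha_v: float = 0.05

    def rpe(self, reward: float) -> float:
        """Return delta = reward - V and update V toward the reward."""
        delta = reward - self.V
        self.V += self.alpha_v * delta
        return delta


@dataclass(frozen=True)
class DAParams:
    """Dopamine and striatal learning-rate constants."""

    burst_gain: float = 0.6   # multiplier on positive RPEs
    dip_gain: float = 0.6     # multiplier on negative RPEs
    #: dopamine firing cannot fall below zero, so dips have a bounded
    #: dynamic range: negative RPEs are clipped at -dip_clip before the
    #: dip gain is applied (bursts are unbounded).  Without this floor,
    #: rare failures at high performance carry RPEs an order of
    #: magnitude larger than the many small successes, and good gating
    #: policies erode themselves.
    dip_clip: float = 0.65
    lrate_go: float = 0.005
    lrate_nogo: float = 0.005
    #: learning-rate scale for omission events (NoGo-tagged silent
    #: gates) relative to executed-gate learning; omission credit is
    #: weaker than action credit, which slows the self-reinforcing
    #: "give up" loop without removing it
    omission_scale: float = 0.25
    #: slow multiplicative forgetting applied at each reward event;
    #: bounds integral windup of unused Go/NoGo weights so that a
    #: collapsed ("given up") policy can be re-explored, while weights
    #: that keep being reinforced are maintained
    w_decay: float = 0.001

    def __post_init__(self) -> None:
        if self.burst_gain < 0 or self.dip_gain < 0:
            raise ValueError("dopamine gains must be >= 0")


@dataclass
class SynapticTags:
    """Eligibility traces over one module's corticostriatal synapses.

    A gating event stamps the presynaptic (control input) activity onto
    the tag vector; tags decay multiplicatively each trial and are
    cleared after every RPE delivery, so only events since the last
    reward carry credit.
    """

    values: np.ndarray
    decay: float = 0.9

    @classmethod
    def zeros(cls, n: int, decay: float = 0.9) -> "SynapticTags":
        return cls(values=np.zeros(n), decay=decay)

    def stamp(self, pre_activity: np.ndarray) -> None:
        # saturating: a synapse's tag is the strongest recent conjunction,
        # so control bits active on every trial cannot accumulate
        # disproportionate credit
        self.values = np.maximum(
            self.values, np.asarray(pre_activity, dtype=float)
        )

    def decay_step(self) -> None:
        self.values = self.values * self.decay

    def clear(self) -> None:
        self.values = np.zeros_like(self.values)

    @property
    def any(self) -> bool:
        return bool(np.any(self.values > 0))


def compute_reward(
    reported: float,
    target: float,
    zero_error_deg: float = REWARD_ZERO_ERROR_DEG,
) -> float:
    """Continuously linear reward from report accuracy.

    reward = 1 - |circular error in degrees| / zero_error_deg, so a
    perfect report earns +1, the reward crosses zero at the closeness
    threshold and is negative beyond it, bounded below at -1 so that
    punishment cannot outweigh the largest attainable reward (keeps the
    critic and plasticity on a symmetric scale).  Non-responses are
    substituted with a uniform random report before scoring (see the
    task module).
    """
    err = abs(circular_error(reported, target))
    return max(1.0 - err / zero_error_deg, -1.0)


def da_modulate(delta: float, params: DAParams) -> float:
    """Dopamine-scale an RPE: bursts for positive, bounded dips for negative.

    effective_delta = burst_gain * delta for delta > 0, and
    dip_gain * max(delta, -dip_clip) for delta <= 0 (the dip bottoms
    out where dopamine firing reaches zero).
    """
    if delta > 0:
        return params.burst_gain * delta
    return params.dip_gain * max(delta, -params.dip_clip)


def update_striatal(
    tags: SynapticTags,
    effective_delta: float,
    params: DAParams,
    go_w: np.ndarray,
    nogo_w: np.ndarray,
    nogo_tags: SynapticTags | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply dopamine-modulated plasticity to one module's Go/NoGo weights.

    ``tags`` mark synapses whose gating event fired (Go-unit activity):
    bursts strengthen their Go weights and weaken the NoGo opponents;
    dips do the reverse, suppressing the punished gating route.
    ``nogo_tags`` mark decisions where the gate stayed silent (NoGo-unit
    activity): a dip strengthens those NoGo weights further (reinforcing
    the suppression) while a burst produces LTD on the active NoGo
    synapses, which is what lets a network recover from a learned
    "give up" state.  Untagged synapses are unchanged; weights stay
    clipped to [0, 1].
    """
    t = tags.values
    go = np.clip(go_w + params.lrate_go * effective_delta * t, 0.0, 1.0)
    nogo = np.clip(nogo_w - params.lrate_nogo * effective_delta * t, 0.0, 1.0)
    if nogo_tags is not None:
        nogo = np.clip(
            nogo
            - params.omission_scale * params.lrate_nogo * effective_delta
            * nogo_tags.values,
            0.0, 1.0,
        )
    if params.w_decay > 0:
        go = go * (1.0 - params.w_decay)
        nogo = nogo * (1.0 - params.w_decay)
    return go, nogo


def gating_policy_metric(
    go_w: np.ndarray,
    nogo_w: np.ndarray,
    orientation_block: slice | np.ndarray = slice(None),
) -> float:
    """Rectified normalized Go-NoGo contrast over the orientation inputs.

    alpha = [ (sum Go - sum NoGo) / (sum Go + sum NoGo) ]+ computed over
    the weights from the control units coding store orientations; when
    NoGo outweighs Go the net drive to thalamus is zero, so alpha is 0.
    Defined as 0 when both sums vanish.
    """
    g = float(np.sum(np.asarray(go_w)[orientation_block]))
    n = float(np.sum(np.asarray(nogo_w)[orientation_block]))
    if g < 0 or n < 0:
        raise ValueError("weight sums must be >= 0")
    if g + n == 0:
        return 0.0
    return max(0.0, (g - n) / (g + n))
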