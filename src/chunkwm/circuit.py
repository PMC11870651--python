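"""Stripe-structured PFC with basal-ganglia gating.

The PFC is divided into isolated "stripes" (independently gateable
memory slots).  Each stripe has a superficial layer that transiently
mirrors its source (the sensory input layer, or the chunk layer), and a
deep maintenance layer that holds a gated bump robustly across trials
with no decay.  Per stripe and per gating type (input / output), a
striatal module with Go and NoGo units reads a control input (the
discrete orientation, task phase, and the stripe's own occupancy); the
gate fires when the noisy Go-minus-NoGo drive is positive, standing in
for striatal disinhibition of thalamocortical updating.  Firing an
input gate loads the stripe's superficial content into maintenance;
firing an output gate at recall copies maintained content to the output
side, from where the (plastic) response pathway reads it out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chunk import ChunkLayerSpec, chunk_settle
from .learning import (
    Critic,
    DAParams,
    SynapticTags,
    da_modulate,
    update_striatal,
)
from .popcode import PopulationBump, decode_color, encode_color
from .readout import OutputMapping, train_step_output
from .task import N_ORIENTATIONS, Trial, score_recall

__all__ = [
    "StripeSpec",
    "BGModule",
    "StripeState",
    "GatingDecision",
    "control_vector",
    "input_gate",
    "maintain",
    "output_gate",
    "count_output_gated",
    "PBWMNetwork",
    "ORIENT_BLOCK",
    "CONTROL_DIM",
]

#: Control-input layout: orientation one-hot, store/recall phase bits,
#: own-stripe empty/occupied bits.
ORIENT_BLOCK = slice(0, N_ORIENTATIONS)
CONTROL_DIM = N_ORIENTATIONS + 4

#: Decoded-output resultant lengths below this count as non-decodable.
NONRESPONSE_RESULTANT_FLOOR = 0.1


def control_vector(
    orientation: int, phase: str, occupied: bool
) -> np.ndarray:
    """Build one stripe's control input for a gating decision."""
    c = np.zeros(CONTROL_DIM)
    c[orientation] = 1.0
    c[N_ORIENTATIONS + (0 if phase == "store" else 1)] = 1.0
    c[N_ORIENTATIONS + 2 + (1 if occupied else 0)] = 1.0
    return c


@dataclass(frozen=True)
class StripeSpec:
    """Which representation feeds this stripe's superficial layer."""

    source: str = "input"  # input | chunk

    def __post_init__(self) -> None:
        if self.source not in ("input", "chunk"):
            raise ValueError(f"unknown stripe source {self.source!r}")


@dataclass
class BGModule:
    """One striatal Go/NoGo module (per stripe, per gating type)."""

    go_w: np.ndarray
    nogo_w: np.ndarray
    noise_sd: float = 0.1
    tags: SynapticTags = field(default=None)  # type: ignore[assignment]
    nogo_tags: SynapticTags = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tags is None:
            self.tags = SynapticTags.zeros(self.go_w.size)
        if self.nogo_tags is None:
            self.nogo_tags = SynapticTags.zeros(self.go_w.size)

    @classmethod
    def random_init(
        cls,
        rng: np.random.Generator,
        n: int = CONTROL_DIM,
        scale: float = 0.05,
        noise_sd: float = 0.1,
    ) -> "BGModule":
        return cls(
            go_w=rng.uniform(0.0, scale, n),
            nogo_w=rng.uniform(0.0, scale, n),
            noise_sd=noise_sd,
        )

    def drive(self, control: np.ndarray, rng: np.random.Generator) -> float:
        """Noisy net Go-minus-NoGo drive for this module."""
        d = float((self.go_w - self.nogo_w) @ control)
        if self.noise_sd > 0:
            d += rng.normal(0.0, self.noise_sd)
        return d


@dataclass
class StripeState:
    """One PFC stripe: source wiring, maintenance content, BG modules."""

    spec: StripeSpec
    bg_in: BGModule
    bg_out: BGModule
    superficial: np.ndarray | None = None
    deep_maint: np.ndarray | None = None
    maintained: bool = False
    out_deep: np.ndarray | None = None

    def clear(self) -> None:
        self.superficial = None
        self.deep_maint = None
        self.maintained = False
        self.out_deep = None


@dataclass(frozen=True)
class GatingDecision:
    trial_index: int
    stripe_index: int
    gate_type: str  # input | output
    fired: bool
    go_minus_nogo: float


def input_gate(
    orientation: int,
    stripes: list[StripeState],
    rng: np.random.Generator,
    trial_index: int = 0,
    competition: float | None = None,
) -> list[GatingDecision]:
    """Per-stripe input-gating decisions on a store trial.

    Each stripe's module sees the shared orientation/phase inputs plus
    its own occupancy bits (state before any gate fires this trial),
    and its noisy Go-minus-NoGo drive is penalized by a fraction of the
    strongest rival drive (mild pallidal competition; several stripes
    can still gate the same stimulus when their drives are close).  A
    firing gate replaces the stripe's maintained content with its
    current superficial content and stamps an eligibility tag; silent
    stripes keep their prior content untouched and stamp the NoGo side.
    """
    if competition is None:
        competition = INPUT_COMPETITION
    occupied_before = [s.maintained for s in stripes]
    raw = []
    for stripe, occ in zip(stripes, occupied_before):
        c = control_vector(orientation, "store", occ)
        raw.append((c, stripe.bg_in.drive(c, rng)))
    decisions = []
    for j, (stripe, (c, d0)) in enumerate(zip(stripes, raw)):
        rival = max(
            (d for k, (_, d) in enumerate(raw) if k != j), default=0.0
        )
        d = d0 - competition * max(rival, 0.0)
        fired = d > 0 and stripe.superficial is not None
        if fired:
            stripe.deep_maint = np.asarray(stripe.superficial).copy()
            stripe.maintained = True
            stripe.bg_in.tags.stamp(c)
        else:
            stripe.bg_in.nogo_tags.stamp(c)
        decisions.append(GatingDecision(trial_index, j, "input", fired, d))
    return decisions


def maintain(stripes: list[StripeState]) -> list[StripeState]:
    """Carry maintenance across a trial boundary.

    Deep maintenance persists losslessly (no decay or drift); the
    superficial layers are transient and will be overwritten by the
    next input, so they are cleared here.
    """
    for s in stripes:
        s.superficial = None
    return stripes


#: Strength of the pallidal/thalamic competition between input gates:
#: weaker than on the output side, so simultaneous multi-stripe input
#: gating of one stimulus remains possible (and is observed in
#: over-provisioned networks), but an occupied stripe with a weakened
#: drive tends to lose the update to an empty rival.
INPUT_COMPETITION = 0.5

#: Strength of the pallidal/thalamic competition between output gates:
#: each stripe's drive is reduced by this fraction of the strongest
#: competing positive drive, so normally a single clear winner is read
#: out, while near-ties (or an undifferentiated policy) still gate out
#: several stripes in parallel.
OUTPUT_COMPETITION = 0.75


def output_gate(
    orientation: int,
    stripes: list[StripeState],
    rng: np.random.Generator,
    trial_index: int = 0,
    competition: float | None = None,
) -> tuple[list[GatingDecision], np.ndarray | None]:
    """Per-stripe output gating at recall; returns decisions and drive.

    Noisy Go-minus-NoGo drives compete: each drive is penalized by a
    fraction of the largest rival drive before thresholding, standing in
    for the selection performed by pallidal/thalamic circuitry so that
    usually a single maintained representation reaches the output side.
    Fired stripes copy maintained content to their output-side deep
    layer; the response pathway receives the mean of all gated-out
    bumps (so reading out two different colors decodes between them).
    Returns ``None`` drive when nothing with content was gated out (a
    non-response candidate).
    """
    if competition is None:
        competition = OUTPUT_COMPETITION
    raw = []
    for j, stripe in enumerate(stripes):
        c = control_vector(orientation, "recall", stripe.maintained)
        raw.append((c, stripe.bg_out.drive(c, rng)))
    decisions = []
    gated: list[np.ndarray] = []
    for j, (stripe, (c, d0)) in enumerate(zip(stripes, raw)):
        rival = max(
            (d for k, (_, d) in enumerate(raw) if k != j), default=0.0
        )
        d = d0 - competition * max(rival, 0.0)
        fired = d > 0
        if fired:
            stripe.bg_out.tags.stamp(c)
            if stripe.maintained and stripe.deep_maint is not None:
                stripe.out_deep = stripe.deep_maint.copy()
                gated.append(stripe.out_deep)
        else:
            stripe.bg_out.nogo_tags.stamp(c)
        decisions.append(GatingDecision(trial_index, j, "output", fired, d))
    drive = np.mean(gated, axis=0) if gated else None
    return decisions, drive


def count_output_gated(decisions: list[GatingDecision]) -> int:
    """Number of stripes whose output gate fired on one recall trial."""
    return sum(1 for d in decisions if d.gate_type == "output" and d.fired)


@dataclass
class TrialRecord:
    """Per-trial observables appended to the run log."""

    kind: str
    orientation: int
    target: float
    reported: float | None = None
    error_deg: float | None = None
    reward: float | None = None
    delta: float | None = None
    non_response: bool = False
    n_output_gated: int = 0
    occupancy: tuple[bool, ...] = ()
    decisions: list[GatingDecision] = field(default_factory=list)
    lag: int | None = None  # trials since the probed item was presented


class PBWMNetwork:
    """The full circuit: stripes, BG gating, critic, response pathway."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_stripes: int = 2,
        chunk: bool = True,
        n_units: int = 20,
        noise_sd: float = 0.1,
        da: DAParams | None = None,
        chunk_spec: ChunkLayerSpec | None = None,
        mapping: OutputMapping | None = None,
        tag_decay: float = 0.9,
        alpha_v: float = 0.05,
        bump_width: float | None = None,
        output_competition: float | None = None,
        input_competition: float | None = None,
    ) -> None:
        if n_stripes < 1:
            raise ValueError("need at least one stripe")
        if chunk and n_stripes < 2:
            raise ValueError("a chunk model needs >= 2 stripes")
        self.n_units = n_units
        self.noise_sd = noise_sd
        self.da = da or DAParams()
        self.critic = Critic(alpha_v=alpha_v)
        self.mapping = mapping or OutputMapping.random_init(
            rng, n_in=n_units, n_out=n_units
        )
        self.chunk_spec = chunk_spec or ChunkLayerSpec(
            n_units=n_units, n_pfc_slots=n_stripes
        )
        from .popcode import DEFAULT_BUMP_WIDTH

        self.bump_width = bump_width or DEFAULT_BUMP_WIDTH
        self.output_competition = (
            OUTPUT_COMPETITION
            if output_competition is None
            else output_competition
        )
        self.input_competition = (
            INPUT_COMPETITION
            if input_competition is None
            else input_competition
        )
        sources = (
            ["chunk"] + ["input"] * (n_stripes - 1)
            if chunk
            else ["input"] * n_stripes
        )
        self.stripes = [
            StripeState(
                spec=StripeSpec(source=src),
                bg_in=BGModule.random_init(rng, noise_sd=noise_sd),
                bg_out=BGModule.random_init(rng, noise_sd=noise_sd),
            )
            for src in sources
        ]
        for s in self.stripes:
            for m in (s.bg_in, s.bg_out):
                m.tags.decay = tag_decay
                m.nogo_tags.decay = tag_decay

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_stripes(self) -> int:
        return len(self.stripes)

    @property
    def is_chunk_model(self) -> bool:
        return any(s.spec.source == "chunk" for s in self.stripes)

    def _modules(self) -> list[BGModule]:
        out = []
        for s in self.stripes:
            out.extend([s.bg_in, s.bg_out])
        return out

    def set_noise(self, noise_sd: float) -> None:
        """Set the striatal exploration noise (used for annealing)."""
        self.noise_sd = noise_sd
        for m in self._modules():
            m.noise_sd = noise_sd

    def reset_episode(self) -> None:
        """Inter-episode reset: clear maintenance, output side, and tags."""
        for s in self.stripes:
            s.clear()
            for m in (s.bg_in, s.bg_out):
                m.tags.clear()
                m.nogo_tags.clear()

    def gating_alphas(self, gate_type: str = "input") -> list[float]:
        """Eq-style gating-policy metric per stripe over orientation inputs."""
        from .learning import gating_policy_metric

        out = []
        for s in self.stripes:
            m = s.bg_in if gate_type == "input" else s.bg_out
            out.append(gating_policy_metric(m.go_w, m.nogo_w, ORIENT_BLOCK))
        return out

    # -- trial execution -----------------------------------------------

    def _maintained_bumps(self) -> list[PopulationBump]:
        return [
            PopulationBump(s.deep_maint)
            for s in self.stripes
            if s.maintained and s.deep_maint is not None
        ]

    def run_store_trial(
        self,
        trial: Trial,
        rng: np.random.Generator,
        learn: bool = True,
        trial_index: int = 0,
    ) -> TrialRecord:
        sens = encode_color(
            trial.color, width=self.bump_width, n_units=self.n_units
        )
        chunk_bump = None
        if self.is_chunk_model:
            chunk_bump = chunk_settle(
                sens, self._maintained_bumps(), self.chunk_spec
            )
        for s in self.stripes:
            s.superficial = (
                chunk_bump.activities
                if s.spec.source == "chunk"
                else sens.activities
            )
        decisions = input_gate(
            trial.orientation, self.stripes, rng, trial_index,
            competition=self.input_competition,
        )
        rec = TrialRecord(
            kind=trial.kind,
            orientation=trial.orientation,
            target=trial.target,
            decisions=decisions,
            occupancy=tuple(s.maintained for s in self.stripes),
        )
        if learn:
            # on store trials the report target is the presented color,
            # so its encoding is the sensory bump itself
            rec.error_deg = train_step_output(
                (sens.activities, None), trial.target, self.mapping,
                target_act=(
                    sens.activities if trial.target == trial.color else None
                ),
            )
        maintain(self.stripes)
        for m in self._modules():
            m.tags.decay_step()
            m.nogo_tags.decay_step()
        return rec

    def run_ignore_trial(
        self,
        trial: Trial,
        rng: np.random.Generator,
        learn: bool = True,
        trial_index: int = 0,
    ) -> TrialRecord:
        # a distractor is processed exactly like a store trial -- whether
        # to gate it is the policy's problem -- but it is never probed.
        return self.run_store_trial(trial, rng, learn, trial_index)

    def run_recall_trial(
        self,
        trial: Trial,
        rng: np.random.Generator,
        learn: bool = True,
        trial_index: int = 0,
    ) -> TrialRecord:
        from .readout import output_activity

        decisions, drive = output_gate(
            trial.orientation, self.stripes, rng, trial_index,
            competition=self.output_competition,
        )
        reported: float | None = None
        resultant = 0.0
        settled_y = None
        if drive is not None:
            out = output_activity(self.mapping, pre_pfc=drive)
            settled_y = out.activities
            dec, resultant = out.decode()
            if np.isfinite(dec):
                reported = dec
        non_response = (
            drive is None or resultant < NONRESPONSE_RESULTANT_FLOOR
        )
        err, reward = score_recall(reported, non_response, trial.target, rng)
        delta = self.critic.rpe(reward) if learn else reward - self.critic.V
        rec = TrialRecord(
            kind="recall",
            orientation=trial.orientation,
            target=trial.target,
            reported=None if non_response else reported,
            error_deg=err,
            reward=reward,
            delta=delta,
            non_response=non_response,
            n_output_gated=count_output_gated(decisions),
            occupancy=tuple(s.maintained for s in self.stripes),
            decisions=decisions,
        )
        if learn:
            eff = da_modulate(delta, self.da)
            for s in self.stripes:
                for m in (s.bg_in, s.bg_out):
                    if m.tags.any or m.nogo_tags.any:
                        m.go_w, m.nogo_w = update_striatal(
                            m.tags, eff, self.da, m.go_w, m.nogo_w,
                            nogo_tags=m.nogo_tags,
                        )
            if drive is not None:
                train_step_output(
                    (None, drive), trial.target, self.mapping,
                    settled=settled_y,
                )
        for m in self._modules():
            m.tags.clear()
            m.nogo_tags.clear()
        for s in self.stripes:
            s.out_deep = None
        return rec

    def run_episode(
        self,
        episode,
        rng: np.random.Generator,
        learn: bool = True,
        reset: bool = True,
    ) -> list[TrialRecord]:
        """Run one episode; returns per-trial records.

        Maintenance (and eligibility) is reset at episode onset: each
        trial sequence starts from an empty working memory.
        """
        if reset:
            self.reset_episode()
        records = []
        presented_at: dict[int, int] = {}
        for idx, trial in enumerate(episode.trials):
            if trial.kind == "store":
                presented_at[trial.orientation] = idx
                rec = self.run_store_trial(trial, rng, learn, idx)
            elif trial.kind == "ignore":
                rec = self.run_ignore_trial(trial, rng, learn, idx)
            else:
                rec = self.run_recall_trial(trial, rng, learn, idx)
                if trial.orientation in presented_at:
                    rec.lag = idx - presented_at[trial.orientation]
            records.append(rec)
        return records
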