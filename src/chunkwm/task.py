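"""Continuous-report color-wheel task: episode generation and scoring.

An episode presents up to ``set_size`` colored/oriented bars one at a
time (store trials; colors i.i.d. uniform on the wheel, orientations
distinct discrete ids), then probes one of the presented orientations
in gray (recall trial) and asks for the associated color.  Reward is a
linear function of the circular report error; a non-response is scored
by substituting a uniform random report, mimicking guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import REWARD_ZERO_ERROR_DEG, compute_reward
from .popcode import circular_error

__all__ = [
    "Trial",
    "Episode",
    "gen_episode",
    "score_recall",
    "ocv",
    "N_ORIENTATIONS",
]

#: Number of discrete orientations; equals the maximum set size.
N_ORIENTATIONS = 4


@dataclass(frozen=True)
class Trial:
    """One task event.

    kind ``store``/``ignore`` trials carry a color and orientation and
    the color is also the report target; ``recall`` trials carry only
    the probed orientation, with the target being the color originally
    presented with that orientation.
    """

    kind: str                  # store | ignore | recall
    orientation: int
    color: float | None        # radians; None on recall
    target: float              # radians; the color to report

    def __post_init__(self) -> None:
        if self.kind not in ("store", "ignore", "recall"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.kind != "recall" and self.color is None:
            raise ValueError("store/ignore trials need a color")


@dataclass(frozen=True)
class Episode:
    """An ordered sequence of store trials followed by a recall probe."""

    set_size: int
    trials: tuple[Trial, ...]

    @property
    def store_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.kind == "store")

    @property
    def recall_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.kind == "recall")


def gen_episode(
    set_size: int,
    rng: np.random.Generator,
    n_store: int | None = None,
    n_orientations: int = N_ORIENTATIONS,
) -> Episode:
    """Generate one episode: k <= set_size stores then one recall probe.

    Colors are i.i.d. uniform on [0, 2pi); orientations are sampled
    without replacement so each appears at most once per episode.  The
    probe picks one presented orientation uniformly, and its target is
    the color shown with that orientation.  Identical generator state
    gives identical episodes.
    """
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    if set_size > n_orientations:
        raise ValueError(
            f"set_size {set_size} exceeds {n_orientations} orientations"
        )
    k = set_size if n_store is None else n_store
    if not 1 <= k <= set_size:
        raise ValueError("n_store must be in [1, set_size]")
    orientations = rng.choice(n_orientations, size=k, replace=False)
    colors = rng.uniform(0.0, 2.0 * np.pi, size=k)
    trials = [
        Trial("store", int(o), float(c), float(c))
        for o, c in zip(orientations, colors)
    ]
    probe_idx = int(rng.integers(k))
    probe = trials[probe_idx]
    trials.append(Trial("recall", probe.orientation, None, probe.target))
    return Episode(set_size=set_size, trials=tuple(trials))


def score_recall(
    reported: float | None,
    non_response: bool,
    target: float,
    rng: np.random.Generator,
    zero_error_deg: float = REWARD_ZERO_ERROR_DEG,
) -> tuple[float, float]:
    """Score one recall: returns (signed error in degrees, reward).

    Non-responses (nothing output-gated, or an undecodable output) are
    replaced by a uniform random report drawn from ``rng`` before
    scoring, so guessing manifests as a flat error distribution.
    """
    if non_response or reported is None or not np.isfinite(reported):
        reported = float(rng.uniform(0.0, 2.0 * np.pi))
    err = circular_error(reported, target)
    reward = compute_reward(reported, target, zero_error_deg)
    return err, reward


def ocv(episode: Episode, probed_orientation: int | None = None) -> float:
    """Out-of-cluster variance: circular spread of the non-probed colors.

    Computed as the circular standard deviation sqrt(-2 ln R) of the
    colors of the items other than the probed one, expressed in
    degrees (R is the mean resultant length).  Low OCV means the other
    items are similar and hence chunkable.  Requires at least two
    "other" items (set size >= 3); otherwise raises ValueError.
    """
    if probed_orientation is None:
        if not episode.recall_trials:
            raise ValueError("episode has no recall probe")
        probed_orientation = episode.recall_trials[0].orientation
    others = [
        t.color for t in episode.store_trials
        if t.orientation != probed_orientation
    ]
    if len(others) < 2:
        raise ValueError("OCV undefined with fewer than 2 non-probed items")
    z = np.mean(np.exp(1j * np.asarray(others)))
    r = min(float(np.abs(z)), 1.0)
    if r == 0.0:
        return 180.0
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
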