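"""Training loops, seed batteries, and the result analyses.

This module runs the full learning loop (settle -> gate -> maintain ->
respond -> reward -> RPE -> plasticity) over epochs of color-wheel
episodes, evaluates trained networks with plasticity frozen, and
implements the analysis suite: error histograms with a
zero-centered-plus-uniform mixture decomposition, stripe-usage and
empty-stripe ("giving up") rates, error binned by out-of-cluster
variance, dopamine burst/dip sweeps, recency curves, and the
closed-form probability that purely random gating succeeds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from .chunk import ChunkLayerSpec
from .circuit import PBWMNetwork
from .learning import DAParams
from .task import N_ORIENTATIONS, gen_episode, ocv

__all__ = [
    "RunConfig",
    "RunLog",
    "train",
    "train_battery",
    "error_histogram",
    "fit_guess_mixture",
    "stripe_usage",
    "ocv_binned_error",
    "da_sweep",
    "recency_curve",
    "guess_probability",
    "enumerate_random_gating",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one training run.

    Defaults follow the study conditions: networks of two stripes (a
    chunk model has exactly one chunk-linked stripe), 500 epochs of 100
    trials (store and recall events both count toward the per-epoch
    trial budget), balanced dopamine gains.  Reduced-scale batteries
    override ``epochs`` and the number of seeds.
    """

    model: str = "chunk"          # chunk | no_chunk
    n_stripes: int = 2
    set_size: int = 2
    epochs: int = 500
    trials_per_epoch: int = 100
    eval_episodes: int = 200
    n_units: int = 20
    noise_sd: float = 0.15
    #: exploration noise is annealed exponentially from noise_sd down to
    #: noise_sd_final over the first anneal_frac of training, then held;
    #: early training explores gating strategies, late training (and
    #: evaluation) exploits the learned policy
    noise_sd_final: float = 0.03
    anneal_frac: float = 0.6
    burst_gain: float = 0.6
    dip_gain: float = 0.6
    dip_clip: float = 0.65
    lrate_go: float = 0.005
    lrate_nogo: float = 0.005
    omission_scale: float = 0.25
    w_decay: float = 0.001
    output_competition: float = 0.75
    input_competition: float = 0.5
    tag_decay: float = 0.9
    alpha_v: float = 0.05
    out_lrate: float = 0.2
    log_training: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("chunk", "no_chunk"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "chunk" and self.n_stripes < 2:
            raise ValueError("a chunk model needs at least 2 stripes")
        if not 2 <= self.set_size <= N_ORIENTATIONS:
            raise ValueError(
                f"set_size must be in [2, {N_ORIENTATIONS}]"
            )
        if self.epochs < 1 or self.trials_per_epoch < 1:
            raise ValueError("epochs and trials_per_epoch must be >= 1")

    def da_params(self) -> DAParams:
        return DAParams(
            burst_gain=self.burst_gain,
            dip_gain=self.dip_gain,
            dip_clip=self.dip_clip,
            lrate_go=self.lrate_go,
            lrate_nogo=self.lrate_nogo,
            omission_scale=self.omission_scale,
            w_decay=self.w_decay,
        )

    def build_network(self, rng: np.random.Generator) -> PBWMNetwork:
        from .readout import OutputMapping

        return PBWMNetwork(
            rng,
            n_stripes=self.n_stripes,
            chunk=self.model == "chunk",
            n_units=self.n_units,
            noise_sd=self.noise_sd,
            da=self.da_params(),
            chunk_spec=ChunkLayerSpec(
                n_units=self.n_units, n_pfc_slots=self.n_stripes
            ),
            mapping=OutputMapping.random_init(
                rng, n_in=self.n_units, n_out=self.n_units,
                lrate=self.out_lrate,
            ),
            tag_decay=self.tag_decay,
            alpha_v=self.alpha_v,
            output_competition=self.output_competition,
            input_competition=self.input_competition,
        )


@dataclass
class RunLog:
    """Per-trial and per-epoch records of one run, as tidy DataFrames."""

    config: RunConfig
    seed: int
    trials: pd.DataFrame
    alphas: pd.DataFrame
    eval: pd.DataFrame

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.alphas.to_csv(out / "alphas.csv", index=False)
        self.eval.to_csv(out / "eval.csv", index=False)
        with open(out / "config.json", "w") as fh:
            json.dump({**asdict(self.config), "seed": self.seed}, fh,
                      indent=2)


def _record_row(rec, epoch: int, trial: int, episode_ocv: float,
                store_index: int | None) -> dict:
    row = {
        "epoch": epoch,
        "trial": trial,
        "kind": rec.kind,
        "orientation": rec.orientation,
        "target": rec.target,
        "reported": rec.reported,
        "error_deg": rec.error_deg,
        "reward": rec.reward,
        "delta": rec.delta,
        "non_response": rec.non_response,
        "n_output_gated": rec.n_output_gated,
        "lag": rec.lag,
        "ocv": episode_ocv,
        "store_index": store_index,
        # compact gating-decision stream: one 0/1 character per stripe
        "fired_in": "".join(
            "1" if d.fired else "0"
            for d in rec.decisions if d.gate_type == "input"
        ),
        "fired_out": "".join(
            "1" if d.fired else "0"
            for d in rec.decisions if d.gate_type == "output"
        ),
    }
    for j, occ in enumerate(rec.occupancy):
        row[f"occ{j}"] = occ
    return row


def _run_episodes(
    net: PBWMNetwork,
    config: RunConfig,
    rng: np.random.Generator,
    n_trials: int | None,
    n_episodes: int | None,
    epoch: int,
    trial_offset: int,
    learn: bool,
    collect: bool,
) -> tuple[list[dict], int]:
    rows: list[dict] = []
    trial = trial_offset
    done_trials = 0
    done_eps = 0
    while True:
        if n_trials is not None and done_trials >= n_trials:
            break
        if n_episodes is not None and done_eps >= n_episodes:
            break
        ep = gen_episode(config.set_size, rng)
        ep_ocv = ocv(ep) if config.set_size >= 3 else float("nan")
        recs = net.run_episode(ep, rng, learn=learn)
        store_seen = 0
        for rec in recs:
            sidx = None
            if rec.kind == "store":
                sidx = store_seen
                store_seen += 1
            if collect:
                rows.append(_record_row(rec, epoch, trial, ep_ocv, sidx))
            trial += 1
            done_trials += 1
        done_eps += 1
    return rows, trial


def train(config: RunConfig, seed: int) -> tuple[PBWMNetwork, RunLog]:
    """Train one network and evaluate it with plasticity frozen.

    Deterministic: a given (config, seed) pair always produces the same
    network and byte-identical logs.  The evaluation phase keeps the
    exploration noise on (gating remains stochastic at test, as during
    the task) but freezes all weights and the critic.
    """
    rng = np.random.default_rng(seed)
    net = config.build_network(rng)
    rows: list[dict] = []
    alpha_rows: list[dict] = []
    trial = 0
    anneal_epochs = max(int(config.anneal_frac * config.epochs), 1)
    for epoch in range(config.epochs):
        frac = min(epoch / anneal_epochs, 1.0)
        net.set_noise(
            config.noise_sd
            * (config.noise_sd_final / config.noise_sd) ** frac
        )
        new_rows, trial = _run_episodes(
            net, config, rng,
            n_trials=config.trials_per_epoch, n_episodes=None,
            epoch=epoch, trial_offset=trial, learn=True,
            collect=config.log_training,
        )
        rows.extend(new_rows)
        for j, a in enumerate(net.gating_alphas("input")):
            alpha_rows.append({
                "epoch": epoch,
                "stripe": j,
                "source": net.stripes[j].spec.source,
                "alpha": a,
            })
    eval_rows, _ = _run_episodes(
        net, config, rng,
        n_trials=None, n_episodes=config.eval_episodes,
        epoch=-1, trial_offset=0, learn=False, collect=True,
    )
    log = RunLog(
        config=config,
        seed=seed,
        trials=pd.DataFrame(rows),
        alphas=pd.DataFrame(alpha_rows),
        eval=pd.DataFrame(eval_rows),
    )
    return net, log


@dataclass
class BatteryResult:
    """Pooled evaluation records and final gating policies over seeds."""

    config: RunConfig
    seeds: list[int]
    eval: pd.DataFrame            # pooled eval rows, with a seed column
    final_alphas: pd.DataFrame    # seed, stripe, source, alpha
    logs: list[RunLog] = field(default_factory=list)


def train_battery(
    config: RunConfig,
    seeds: list[int],
    keep_logs: bool = False,
) -> BatteryResult:
    """Train a battery of seeds and pool their frozen-weight evaluations."""
    eval_frames = []
    alpha_rows = []
    logs = []
    for seed in seeds:
        net, log = train(config, seed)
        ev = log.eval.copy()
        ev["seed"] = seed
        eval_frames.append(ev)
        for j, a in enumerate(net.gating_alphas("input")):
            alpha_rows.append({
                "seed": seed,
                "stripe": j,
                "source": net.stripes[j].spec.source,
                "alpha": a,
            })
        if keep_logs:
            logs.append(log)
    return BatteryResult(
        config=config,
        seeds=list(seeds),
        eval=pd.concat(eval_frames, ignore_index=True),
        final_alphas=pd.DataFrame(alpha_rows),
        logs=logs,
    )


# -- analyses ----------------------------------------------------------


def error_histogram(
    errors_deg: np.ndarray,
    bins: np.ndarray | None = None,
) -> dict:
    """Histogram of recall errors plus mixture summary statistics.

    Returns bin edges and counts over (-180, 180], the central density
    (fraction of |error| <= 15 degrees), and the uniform-guess weight
    of a zero-centered von Mises + uniform mixture fit.
    """
    errors = np.asarray(errors_deg, dtype=float)
    errors = errors[np.isfinite(errors)]
    if bins is None:
        bins = np.arange(-180.0, 181.0, 15.0)
    counts, edges = np.histogram(errors, bins=bins)
    guess_w, kappa = fit_guess_mixture(errors)
    return {
        "edges": edges,
        "counts": counts,
        "n": errors.size,
        "central_density": float(np.mean(np.abs(errors) <= 15.0))
        if errors.size else float("nan"),
        "guess_weight": guess_w,
        "kappa": kappa,
    }


def _a1inv(r: float) -> float:
    """Approximate inverse of I1(k)/I0(k) (Fisher's approximation)."""
    if r < 0.53:
        return 2 * r + r ** 3 + (5 * r ** 5) / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1 / (r ** 3 - 4 * r ** 2 + 3 * r)


def fit_guess_mixture(
    errors_deg: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """EM fit of a uniform + zero-centered von Mises mixture.

    Models the recall-error distribution as guessing (uniform on the
    circle) plus memory-based responses (von Mises at 0).  Returns
    ``(guess_weight, kappa)``.
    """
    x = np.radians(np.asarray(errors_deg, dtype=float))
    x = x[np.isfinite(x)]
    if x.size < 5:
        return float("nan"), float("nan")
    w = 0.3
    kappa = 5.0
    f_u = 1.0 / (2 * np.pi)
    for _ in range(max_iter):
        f_vm = np.exp(kappa * np.cos(x)) / (2 * np.pi * i0(kappa))
        denom = w * f_u + (1 - w) * f_vm
        resp_u = w * f_u / denom
        w_new = float(resp_u.mean())
        wt = 1.0 - resp_u
        s = wt.sum()
        if s <= 1e-12:
            w = 1.0
            kappa = 0.0
            break
        # kappa is floored at 2 so the memory component stays genuinely
        # peaked; otherwise a near-flat von Mises and the uniform trade
        # off arbitrarily on guess-heavy data
        r = float(np.abs(np.sum(wt * np.exp(1j * x))) / s)
        kappa_new = float(np.clip(_a1inv(min(r, 0.999)), 2.0, 500.0))
        if abs(w_new - w) < tol and abs(kappa_new - kappa) < 1e-3:
            w, kappa = w_new, kappa_new
            break
        w, kappa = w_new, kappa_new
    return float(w), float(kappa)


def _maximal_load_store(eval_df: pd.DataFrame, set_size: int) -> pd.DataFrame:
    df = eval_df
    return df[(df["kind"] == "store") & (df["store_index"] == set_size - 1)]


def stripe_usage(eval_df: pd.DataFrame, set_size: int,
                 n_stripes: int) -> dict:
    """Occupancy rates on maximal-load store trials.

    Returns per-stripe occupancy fractions, the fraction of such trials
    with every stripe occupied, and the fraction with at least one
    empty stripe (the "giving up" signature).
    """
    df = _maximal_load_store(eval_df, set_size)
    occ_cols = [f"occ{j}" for j in range(n_stripes)]
    if df.empty:
        nan = float("nan")
        return {"per_stripe": [nan] * n_stripes, "all_occupied": nan,
                "empty_stripe_rate": nan, "n_trials": 0}
    occ = df[occ_cols].to_numpy(dtype=bool)
    return {
        "per_stripe": occ.mean(axis=0).tolist(),
        "all_occupied": float(occ.all(axis=1).mean()),
        "empty_stripe_rate": float((~occ).any(axis=1).mean()),
        "n_trials": int(len(df)),
    }


def ocv_binned_error(
    eval_df: pd.DataFrame,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean absolute recall error binned by episode out-of-cluster variance."""
    if bins is None:
        bins = np.array([0.0, 30.0, 60.0, 90.0, 180.0])
    df = eval_df[(eval_df["kind"] == "recall")
                 & np.isfinite(eval_df["ocv"])].copy()
    df["abs_err"] = df["error_deg"].abs()
    df["ocv_bin"] = pd.cut(df["ocv"], bins=bins, include_lowest=True)
    out = (
        df.groupby("ocv_bin", observed=True)["abs_err"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_abs_error", "count": "n"})
    )
    return out


def recency_curve(eval_df: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute recall error vs trials since the item was presented."""
    df = eval_df[(eval_df["kind"] == "recall")
                 & eval_df["lag"].notna()].copy()
    df["abs_err"] = df["error_deg"].abs()
    out = (
        df.groupby("lag")["abs_err"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_abs_error", "count": "n"})
    )
    out["lag"] = out["lag"].astype(int)
    return out.sort_values("lag").reset_index(drop=True)


def da_sweep(
    burst_gains: np.ndarray,
    dip_gains: np.ndarray,
    config: RunConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Train reduced batteries per dopamine-gain cell.

    Returns one row per (burst_gain, dip_gain) with the mean absolute
    recall error, non-response rate, and empty-stripe rate pooled over
    seeds.
    """
    from dataclasses import replace

    rows = []
    for bg in burst_gains:
        for dg in dip_gains:
            cfg = replace(config, burst_gain=float(bg), dip_gain=float(dg),
                          log_training=False)
            res = train_battery(cfg, seeds)
            rec = res.eval[res.eval["kind"] == "recall"]
            usage = stripe_usage(res.eval, cfg.set_size, cfg.n_stripes)
            rows.append({
                "burst_gain": float(bg),
                "dip_gain": float(dg),
                "mean_abs_error": float(rec["error_deg"].abs().mean()),
                "non_response_rate": float(rec["non_response"].mean()),
                "empty_stripe_rate": usage["empty_stripe_rate"],
                "all_occupied": usage["all_occupied"],
                "n_recalls": int(len(rec)),
            })
    return pd.DataFrame(rows)


# -- combinatorial baseline -------------------------------------------


def guess_probability(n_stripes: int, set_size: int) -> float:
    """Probability that uniformly random gating stores and reads out
    the probed item: (n-1)^(N-1) / n^N for n stripes and set size N.

    Each item is input-gated into a uniformly random stripe (later
    items may overwrite earlier ones) and a single uniformly random
    stripe is output-gated at recall; success requires the probed
    (first) item to survive un-overwritten and be the one read out.
    """
    n, N = n_stripes, set_size
    if n < 1 or N < 1:
        raise ValueError("n_stripes and set_size must be >= 1")
    return (n - 1) ** (N - 1) / n ** N


def enumerate_random_gating(n_stripes: int, set_size: int) -> float:
    """Brute-force check of ``guess_probability`` by full enumeration.

    Enumerates every equally likely combination of input-gate stripe
    assignments (one per item, in presentation order, overwriting) and
    output-gate choice, and counts outcomes where the first item is
    still stored un-overwritten in the stripe that gets read out.
    """
    n, N = n_stripes, set_size
    total = 0
    success = 0
    for assign in itertools.product(range(n), repeat=N):
        for out_choice in range(n):
            total += 1
            if all(a != assign[0] for a in assign[1:]) \
                    and out_choice == assign[0]:
                success += 1
    return success / total
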