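"""Shared fixtures: reduced-scale trained seed batteries.

The behavioral acceptance tests all evaluate trained networks; training
is by far the dominant cost, so one session-scoped battery (10 seeds per
model per set size, 100 epochs of 100 trials — the study conditions
scaled down) is trained once and shared across the stripe-usage,
error-mixture, OCV, recency, and gating-policy tests.
"""

import numpy as np
import pytest

from chunkwm.experiments import RunConfig, train_battery

BATTERY_SEEDS = list(range(1, 11))
BATTERY_EPOCHS = 150
BATTERY_EVAL_EPISODES = 100


def _config(model: str, set_size: int, n_stripes: int = 2) -> RunConfig:
    return RunConfig(
        model=model,
        set_size=set_size,
        n_stripes=n_stripes,
        epochs=BATTERY_EPOCHS,
        eval_episodes=BATTERY_EVAL_EPISODES,
        log_training=False,
    )


@pytest.fixture(scope="session")
def battery():
    """Trained two-stripe batteries: (model, set_size) -> BatteryResult."""
    out = {}
    for model in ("chunk", "no_chunk"):
        for set_size in (2, 3, 4):
            out[(model, set_size)] = train_battery(
                _config(model, set_size), BATTERY_SEEDS
            )
    return out


@pytest.fixture(scope="session")
def battery_8stripe():
    """No-chunk networks with eight stripes at set size 4 (reduced)."""
    return train_battery(
        _config("no_chunk", 4, n_stripes=8), BATTERY_SEEDS[:4]
    )


def recall_errors(result) -> np.ndarray:
    rec = result.eval[result.eval["kind"] == "recall"]
    return rec["error_deg"].to_numpy(dtype=float)
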