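"""Flat configuration schema for runs (YAML or JSON).

Every tunable constant of the simulator is surfaced here with its
default; unknown keys are rejected so that typos fail loudly rather
than silently running the default.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import yaml

from .experiments import RunConfig

__all__ = ["load_config", "config_to_dict", "CONFIG_FIELDS"]

CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def load_config(path: str | pathlib.Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Raises ValueError on unknown keys; file values are overridden by
    any non-None entries in ``overrides`` (e.g. command-line flags).
    """
    data: dict = {}
    if path is not None:
        text = pathlib.Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - set(CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)
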