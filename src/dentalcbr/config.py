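"""Run configuration: one master seed, per-component defaults, YAML IO.

The YAML file mirrors the nested structure below; unknown keys are
rejected so typos fail loudly.  Every stochastic component receives a
seed derived deterministically from the master seed, so a run is fully
reproducible from (config file, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cbr_engine import EngineConfig


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorOptions:
    n_cases: int = 3000
    censoring_fraction: float = 0.6


@dataclass
class RunConfig:
    seed: int = 0
    reference_date: str = "2014-06-30"
    generator: GeneratorOptions = field(default_factory=GeneratorOptions)
    engine: EngineConfig = field(default_factory=EngineConfig)

    @property
    def reference(self) -> dt.date:
        return dt.date.fromisoformat(self.reference_date)

    def component_seed(self, *tags: int) -> int:
        """A child seed derived from the master seed (always < 2**31)."""
        return int(
            np.random.default_rng(np.random.SeedSequence([self.seed, *tags])).integers(0, 2**31 - 1)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _merge(target, data: dict, path: str = "") -> None:
    valid = {f.name: f for f in dataclasses.fields(target)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        current = getattr(target, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge(current, value, path=f"{path}{key}.")
        else:
            setattr(target, key, value)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        _merge(cfg, data)
    if overrides:
        _merge(cfg, overrides)
    return cfg


def write_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(RunConfig().to_dict(), fh, sort_keys=False)
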