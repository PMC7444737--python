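"""Run configuration: schema validation and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["AnalysisConfig", "ConfigError", "config_hash", "load_config"]


class ConfigError(ValueError):
    """Raised for schema violations; the CLI maps it to exit code 2."""


@dataclass
class AnalysisConfig:
    """Settings for the classify/permtest stages.

    ``grid_c`` / ``grid_gamma`` are base-2 exponents; an empty grid means
    fixed default hyperparameters (C = 1, gamma = 1/p).
    """

    k: int = 10
    inner_k: int = 5
    grid_c: list = field(default_factory=list)
    grid_gamma: list = field(default_factory=list)
    n_perm: int = 5000
    alpha: float = 0.05
    perm_retune: bool = False
    clean_stage: str = "voxel"
    confounds: list = field(default_factory=lambda: ["age"])
    seed: int = 0
    workers: int = 1

    def validate(self) -> "AnalysisConfig":
        if self.k < 2 or self.inner_k < 2:
            raise ConfigError("k and inner_k must be >= 2")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.clean_stage not in ("voxel", "parcel"):
            raise ConfigError("clean_stage must be 'voxel' or 'parcel'")
        if bool(self.grid_c) != bool(self.grid_gamma):
            raise ConfigError("grid_c and grid_gamma must be given together")
        known = {"age", "mean_fd", "gmv_total"}
        bad = set(self.confounds) - known
        if bad:
            raise ConfigError(f"unknown confound(s): {sorted(bad)}")
        return self

    def grid(self):
        from .classify import HyperParams

        if not self.grid_c:
            return None
        return [HyperParams(c=2.0**ec, gamma=2.0**eg)
                for ec in self.grid_c for eg in self.grid_gamma]


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        cfg = AnalysisConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return cfg.validate()


def config_hash(obj) -> str:
    """Stable hash of a config (dataclass or dict) for artifact provenance."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
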