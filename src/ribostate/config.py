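"""Run configuration: YAML schema, validation and hashing.

A run is a pure function of (inputs, config, seed); the config hash is
stamped into every output table header so reports are traceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError"]

_STAGES = ("simulate", "energy", "decompose", "entropy", "geometry", "states", "report")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "ribostate_out"
    temperature: float = 300.0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    energy_params: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    selections: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] | None = None
    derive_thresholds: dict[str, float] | None = None
    distances: list[dict[str, str]] = field(default_factory=list)
    hbonds: dict[str, float] = field(default_factory=lambda: {"dist_cut": 3.5, "angle_cut": 135.0})
    n_replicas: int = 1
    snapshot_fraction: float = 0.5  # trailing fraction of each replica analysed
    snapshot_stride: int = 1
    entropy_stride: int = 10  # entropy uses every Nth analysis snapshot
    raw: dict[str, Any] = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        cfg.raw = data
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        for s in self.stages:
            if s not in _STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid: {_STAGES}")
        if self.thresholds is not None and self.derive_thresholds is not None:
            raise ConfigError("give either thresholds or derive_thresholds, not both")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if not 0 < self.snapshot_fraction <= 1:
            raise ConfigError("snapshot_fraction must be in (0, 1]")
        if self.n_replicas < 1:
            raise ConfigError("n_replicas must be >= 1")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {key!r}: path {path!r} does not exist")
        if self.thresholds is not None:
            if set(self.thresholds) != {"closed_max", "open_min"}:
                raise ConfigError("thresholds needs closed_max and open_min")
            if not self.thresholds["closed_max"] < self.thresholds["open_min"]:
                raise ConfigError("thresholds: closed_max must be < open_min")
        for dd in self.distances:
            if not {"label", "group_a", "group_b"} <= set(dd):
                raise ConfigError("each distance needs label/group_a/group_b")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw or {}, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def overrides(self) -> dict[str, Any]:
        """Keys explicitly set in the source config (reported in headers)."""
        return {k: v for k, v in (self.raw or {}).items() if k != "raw"}
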