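"""Run configuration: every tunable analysis parameter in one place.

Defaults reproduce the experimental protocol values (75 ms response
window, 4x baseline-SD significance threshold, 100 um pairing distance,
70% density contour). Unknown keys are rejected on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    # sCRACM analysis
    window_ms: float = 75.0
    baseline_ms: float = 100.0
    threshold_mult: float = 4.0
    pair_dist_um: float = 100.0
    # hierarchy analysis
    contour_fraction: float = 0.70
    contour_method: str = "range"
    contour_scope: str = "band"
    filter_radius: int = 10
    ff_threshold: float = 1.0
    # paired-recording analysis
    k_sd: float = 4.0
    spike_threshold_mv: float = 0.0
    refractory_ms: float = 2.0
    # simulation overrides, validated downstream against the generator
    simulate: dict | None = None

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.baseline_ms <= 0:
            raise ConfigError("windows must be positive")
        if self.threshold_mult < 0 or self.k_sd < 0:
            raise ConfigError("SD multipliers must be non-negative")
        if not 0 < self.contour_fraction <= 1:
            raise ConfigError("contour_fraction must be in (0, 1]")
        if self.filter_radius < 1:
            raise ConfigError("filter_radius must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Short stable digest embedded in every output artifact."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
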