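"""Run configuration: every tunable default in one serializable object.

The YAML schema is versioned and strict — unknown keys are rejected rather
than ignored, because a silently misspelt key would quietly change a method
definition.  The configuration hash is recorded in all outputs so a metric
CSV can always be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline defaults, overridable from YAML.

    Detection: ``min_drop_pct``/``max_window_s`` per the 3%-drop, 180-s-cap
    convention; recovery/plateau tolerances are this package's documented
    choices.  Windows: ensemble span and smoothing for the record-specific
    window, the fixed-window geometry flag, the 100-s event-baseline
    lookback.  Areas: overlap policy.  Survival: z-score convention.
    """

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    # cleaning
    max_gap_s: float = 30.0
    exclude_wake_events: bool = False
    # detection
    min_drop_pct: float = 3.0
    max_window_s: float = 180.0
    recovery_tolerance_pct: float = 1.0
    plateau_tolerance_pct: float = 0.5
    smoothing_window_s: float = 0.0
    # windows / baselines
    ensemble_span_pre_s: float = 120.0
    ensemble_span_post_s: float = 240.0
    ensemble_smooth_s: float = 10.0
    ensemble_min_events: int = 5
    baseline_lookback_s: float = 100.0
    fixed_window_ends_at_2p5T: bool = False
    # area engine
    overlap_policy: str = "truncate"
    # survival
    population_sd: bool = True
    minsat_mode: str = "min_over_windows"

    def __post_init__(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version} (expected {SCHEMA_VERSION})"
            )
        if self.overlap_policy not in ("truncate", "none"):
            raise ConfigError(f"unknown overlap_policy {self.overlap_policy!r}")
        if self.minsat_mode not in ("min_over_windows", "mean_of_nadirs"):
            raise ConfigError(f"unknown minsat_mode {self.minsat_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def detection_params(self):
        from .detection import DetectionParams

        return DetectionParams(
            min_drop_pct=self.min_drop_pct,
            max_window_s=self.max_window_s,
            recovery_tolerance_pct=self.recovery_tolerance_pct,
            plateau_tolerance_pct=self.plateau_tolerance_pct,
            smoothing_window_s=self.smoothing_window_s,
        )

    def ensemble_kwargs(self) -> dict:
        return dict(
            span_pre_s=self.ensemble_span_pre_s,
            span_post_s=self.ensemble_span_post_s,
            smooth_s=self.ensemble_smooth_s,
            min_events=self.ensemble_min_events,
        )
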