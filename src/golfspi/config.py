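"""Run configuration: marker mapping, detection thresholds, seeds.

A ``RunConfig`` collects every tunable the command-line pipeline exposes
and round-trips losslessly through YAML, so an analysis can be re-run
byte-identically from its config file and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .marker_io import DEFAULT_ROLE_MAP, VALID_VERTICAL


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # marker label -> role mapping used by the TRC reader
    markers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))
    vertical_axis: str = "z+"
    units: str = "m"
    handedness: str = "right"
    # event-detection thresholds
    backswing_threshold: float = 0.2  # m/s vertical club speed
    min_hold: int = 5  # frames the threshold must be sustained
    ball_launch_threshold: float = 0.5  # m/s
    ball_static_tol: float = 0.05  # m/s
    filter_cutoff_hz: float | None = None  # optional zero-lag low-pass
    max_gap: int = 10  # frames of marker dropout to interpolate
    # model-selection settings
    kmo_threshold: float = 0.6
    kmo_population: str = "original"  # {original, balanced, pro_only}
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("backswing_threshold", "ball_launch_threshold", "ball_static_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_hold < 1 or self.max_gap < 0:
            raise ConfigError("min_hold must be >= 1 and max_gap >= 0")
        if self.vertical_axis not in VALID_VERTICAL:
            raise ConfigError(f"vertical_axis must be one of {VALID_VERTICAL}")
        if self.kmo_population not in ("original", "balanced", "pro_only"):
            raise ConfigError(f"unknown kmo_population {self.kmo_population!r}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config file must be a mapping")
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)
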