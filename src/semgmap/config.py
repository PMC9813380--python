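"""Pipeline configuration: defaults, YAML round-trip, validation.

Defaults reproduce the study conditions: an 8 x 8 grid at 10 mm IED
sampled at 2,048 Hz, a 20-400 Hz band, six window lengths crossed with
five overlaps, and a 60 %-of-maximum trapezoidal contraction whose
plateau yields 10,240 samples.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .maps import DEFAULT_OVERLAPS_PCT, DEFAULT_WINDOWS_MS


@dataclass
class PipelineConfig:
    # simulation
    n_units: int = 60
    active_center: tuple[float, float] = (3.5, 3.5)
    spread_mm: float = 10.0
    level: float = 0.6
    noise_rms: float = 0.05
    n_trials: int = 1
    fs_hz: float = 2048.0
    plateau_samples: int = 10_240
    bad_channels: tuple[int, ...] = ()
    bad_channel_gain: float = 100.0
    # preprocessing
    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    filter_order: int = 2
    z_threshold: float = 3.0
    # segmentation design
    windows_ms: tuple[float, ...] = DEFAULT_WINDOWS_MS
    overlaps_pct: tuple[float, ...] = DEFAULT_OVERLAPS_PCT
    intensity: str = "rms"
    # embedding
    backend: str = "linear"
    n_neighbors: int = 10
    min_dist: float = 0.7
    voxel_grid: int = 16
    # stats
    alpha: float = 0.05
    k_max: int = 6
    cluster_subsample: int = 300
    # bookkeeping
    seed: int = 0
    out_dir: str = "semgmap_run"

    def __post_init__(self) -> None:
        errors = []
        if self.n_units < 1:
            errors.append("n_units must be >= 1")
        if not 0 < self.level <= 1:
            errors.append("level must lie in (0, 1]")
        if self.noise_rms < 0:
            errors.append("noise_rms must be non-negative")
        if self.n_trials < 1:
            errors.append("n_trials must be >= 1")
        if any(not 0 <= ov < 100 for ov in self.overlaps_pct):
            errors.append("overlaps must lie in [0, 100)")
        if any(w <= 0 for w in self.windows_ms):
            errors.append("window lengths must be positive")
        if self.intensity not in ("rms", "mean_square"):
            errors.append(f"unknown intensity mode {self.intensity!r}")
        if self.backend not in ("manifold", "linear"):
            errors.append(f"unknown embedding backend {self.backend!r}")
        if not 0 < self.alpha < 1:
            errors.append("alpha must lie in (0, 1)")
        if errors:
            raise ValidationError("; ".join(errors))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed; adding stages never shifts streams."""
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("active_center", "bad_channels", "windows_ms", "overlaps_pct"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        kwargs = dict(d)
        for key in ("active_center", "bad_channels", "windows_ms", "overlaps_pct"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; an empty file yields the full default config."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    return PipelineConfig.from_dict(raw)


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
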