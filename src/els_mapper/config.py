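"""Pipeline configuration with validation and lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class DetectionParams:
    min_sigma_um: float = 2.5
    max_sigma_um: float = 5.0
    threshold: float = 0.3
    coloc_radius_um: float = 5.0
    bt_radius_um: float = 2.5  # B-vs-T double-positive resolution radius
    eps_um: float = 50.0
    min_cells: int = 10

    def validate(self):
        if self.min_sigma_um <= 0 or self.max_sigma_um < self.min_sigma_um:
            raise ConfigError("invalid spot-scale range")
        if self.threshold < 0:
            raise ConfigError("threshold must be >= 0")
        if self.coloc_radius_um <= 0:
            raise ConfigError("coloc_radius_um must be > 0")
        if self.bt_radius_um <= 0:
            raise ConfigError("bt_radius_um must be > 0")
        if self.eps_um <= 0:
            raise ConfigError("eps_um must be > 0")
        if self.min_cells < 3:
            raise ConfigError("min_cells must be >= 3")


@dataclass
class ScoringParams:
    k: int = 5
    n_perm: int = 999
    alpha: float = 0.05
    p_prolif: float = 0.05
    min_minority: int = 5

    def validate(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.n_perm < 99:
            raise ConfigError("n_perm must be >= 99")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 <= self.p_prolif <= 1:
            raise ConfigError("p_prolif must be in [0, 1]")
        if self.min_minority < 1:
            raise ConfigError("min_minority must be >= 1")


@dataclass
class SpatialParams:
    hex_diameter: float = 0.05
    circle_scale: float = 2e-4
    pooled: bool = True

    def validate(self):
        if self.hex_diameter <= 0:
            raise ConfigError("hex_diameter must be > 0")
        if self.circle_scale <= 0:
            raise ConfigError("circle_scale must be > 0")


@dataclass
class StatsParams:
    # numeric coding of age groups for correlation/regression
    age_coding: dict = field(default_factory=lambda: {"1": 1.0, "12": 12.0, "18+": 18.0})
    bell_model: str = "quadratic"

    def validate(self):
        if self.bell_model not in ("quadratic", "gaussian"):
            raise ConfigError("bell_model must be 'quadratic' or 'gaussian'")
        if not self.age_coding:
            raise ConfigError("age_coding must be non-empty")


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        for section in (self.detection, self.scoring, self.spatial, self.stats):
            section.validate()
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        return cls(
            detection=DetectionParams(**d.get("detection", {})),
            scoring=ScoringParams(**d.get("scoring", {})),
            spatial=SpatialParams(**d.get("spatial", {})),
            stats=StatsParams(**d.get("stats", {})),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
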