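"""Pipeline configuration: one YAML document drives every stage.

All fixed analysis constants live here with their conventional defaults
(200-m shelf rule, 12-h trip-end trim, 100 candidate tracks, 6-day
exclusion window, 10 replicates, mtry grid {2,3,4}, 500 trees, node size 1,
10 CV folds, Jul-Oct weeks, 375-km accessibility radius, top-25% core
quantile).  Validation errors name the offending field.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .prediction import COLD_YEARS, WARM_YEARS


@dataclass
class PipelineConfig:
    # paths
    env_path: str = "env.nc"
    telemetry_path: str = "trips.csv"
    catch_path: str = "catch.csv"
    outdir: str = "out"
    # reproducibility
    seed: int = 0
    # synthetic-data scale
    n_animals: int = 40
    trips_per_animal: int = 3
    years: list = field(default_factory=lambda: [2015, 2016, 2017])
    grid_nlon: int = 60
    grid_nlat: int = 60
    selection_strength: float = 0.0
    # analysis constants
    shelf_depth_m: float = 200.0
    trim_hours: int = 12
    n_candidates: int = 100
    filter_window_days: int = 6
    n_replicates: int = 10
    mtry_grid: list = field(default_factory=lambda: [2, 3, 4])
    n_trees: int = 500
    min_node_size: int = 1
    cv_folds: int = 10
    weeks: list = field(default_factory=lambda: list(range(27, 45)))
    crop_radius_km: float = 375.0
    core_quantile: float = 0.75
    warm_years: list = field(default_factory=lambda: list(WARM_YEARS))
    cold_years: list = field(default_factory=lambda: list(COLD_YEARS))
    # projection scenarios: name + per-variable ESM bias and per-decade drift
    scenarios: list = field(default_factory=lambda: [
        {"name": "esm-warm-ssp585",
         "esm_bias": {"temp_surface": 1.0, "temp_bottom": 0.5},
         "drift": {"temp_surface": 0.6, "temp_bottom": 0.4}},
    ])
    future_years: list = field(default_factory=lambda: [2055, 2056])
    rookery: list | None = None  # [lon, lat]; default chosen on the shelf

    def validate(self) -> None:
        positive = ("trim_hours", "n_candidates", "filter_window_days", "n_replicates",
                    "n_trees", "min_node_size", "cv_folds", "crop_radius_km",
                    "shelf_depth_m", "n_animals", "trips_per_animal")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field '{name}' must be positive")
        if not (0.0 < self.core_quantile < 1.0):
            raise ValueError("config field 'core_quantile' must lie in (0, 1)")
        if set(self.warm_years) & set(self.cold_years):
            raise ValueError("config fields 'warm_years'/'cold_years' must be disjoint")
        if any(m < 1 for m in self.mtry_grid):
            raise ValueError("config field 'mtry_grid' entries must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
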