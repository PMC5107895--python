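"""Pipeline configuration: one validated YAML document drives every stage."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class WorldConfig(BaseModel):
    """Synthetic-world generation knobs (ignored when real inputs are given)."""

    extent: tuple[float, float, float, float] = (0.0, 16.0, 30.0, 46.0)
    resolution: float = Field(0.08, gt=0)
    n_presences: int = Field(150, ge=0)
    n_seamounts: int = Field(3, ge=0)
    effort_west_bias: float = Field(3.0, gt=0)
    niche_lo: float = 14.0           # lower thermal limit (°C)
    niche_hi: float = 24.0           # upper thermal limit (°C)
    niche_softness: float = Field(0.15, gt=0)
    hard_bottom_fraction: float = Field(0.4, ge=0, le=1)
    n_mpas: int = Field(5, ge=0)
    n_bottles: int = Field(300, ge=0)
    bottle_noise_sd: float = Field(0.0, ge=0)


class PipelineConfig(BaseModel):
    """All numeric knobs of the analysis, with literature defaults."""

    seed: int = 0
    out_dir: Path = Path("runs/default")

    # predictor construction
    depth_min_m: float = 15.0
    depth_max_m: float = 200.0
    predictor_spec: list[tuple[str, str]] = [
        ("temperature", "min"), ("temperature", "max"),
        ("salinity", "min"), ("nitrate", "max"), ("npp", "min"),
    ]
    include_slope: bool = True

    # occurrence processing
    mantel_class_width_km: float = Field(2.5, gt=0)
    mantel_max_dist_km: float = Field(50.0, gt=0)
    mantel_n_perm: int = Field(9999, ge=9)
    mantel_alpha: float = Field(0.05, gt=0, lt=1)

    # pseudo-absence generation
    esm_threshold: float = Field(0.2, gt=0, lt=1)
    effort_bandwidth_km: float | None = None  # default: Mantel range

    # model tuning and spatial CV
    r_max: float = Field(0.8, gt=0, le=1)
    min_combo_size: int = Field(2, ge=1)
    max_combo_size: int | None = None
    max_combinations: int = Field(500, ge=1)
    lr_grid: list[float] = [0.01, 0.005, 0.001, 0.0005]
    tc_max: int | None = None
    bag_fraction: float = Field(0.5, gt=0, le=1)
    min_trees: int = Field(1000, ge=1)
    n_trees: int = Field(2000, ge=1)
    n_folds: int = Field(10, ge=2)
    alpha: float = Field(0.05, gt=0, lt=1)

    # reporting
    mesophotic_cutoff_m: float = 50.0

    world: WorldConfig = WorldConfig()

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.depth_min_m >= self.depth_max_m:
            raise ValueError("depth window must satisfy min < max")
        if self.n_trees < self.min_trees:
            raise ValueError(f"n_trees must be >= min_trees ({self.min_trees})")
        if any(lr <= 0 for lr in self.lr_grid):
            raise ValueError("learning rates must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def fast_profile(**overrides) -> PipelineConfig:
    """A scaled-down tuning profile for minutes-scale end-to-end runs.

    Restricts the hyperparameter grid (lr in {0.01, 0.005}, 1000 trees),
    combination sizes (2-3) and Mantel permutations, keeping every
    scientific default (ESM threshold, collinearity cap, folds, alpha,
    depth window, tc from 1 to the combination size) unchanged.
    """
    base = dict(
        lr_grid=[0.01, 0.005],
        n_trees=1000,
        max_combo_size=3,
        mantel_n_perm=999,
    )
    base.update(overrides)
    return PipelineConfig(**base)
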