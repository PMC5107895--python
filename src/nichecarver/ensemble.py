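"""Median-ensemble prediction, reclassification, substrate masking and
area / protection accounting.

The selected combinations are refitted on the full record set, predicted
over every valid cell, and merged cell-wise with a median (uncertainty =
ensemble SD).  The median surface is reclassified at the threshold that
maximizes sensitivity + specificity on the full data, optionally intersected
with the hard-bottom mask, and summarised as habitat area, MPA overlap and
depth stratification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import shapely

from .brt import BRTModel, fit_brt
from .cv import ConfusionStats, CVResult, evaluate_tss
from .grids import Raster, cell_area_km2, total_area_km2
from .predictors import stack_predictors


@dataclasses.dataclass
class EnsembleOutput:
    median: Raster
    sd: Raster
    binary: Raster               # environment-only presence/absence
    binary_rock: Raster | None   # after hard-bottom interception
    threshold: float
    stats: ConfusionStats        # on the full record set
    members: list[BRTModel]
    member_combos: list[tuple[str, ...]]


def refit_members(selected: list[CVResult], data: pd.DataFrame,
                  monotone: dict[str, int]) -> list[BRTModel]:
    """Refit each selected combination on the full record set at its tuned
    hyperparameters."""
    y = data["y"].to_numpy(dtype=float)
    models = []
    for res in selected:
        X = data.loc[:, list(res.combination)].to_numpy(dtype=float)
        signs = tuple(monotone.get(n, 0) for n in res.combination)
        params = dataclasses.replace(res.best_params, monotone=signs)
        models.append(fit_brt(X, y, params, list(res.combination)))
    return models


def build_ensemble(selected: list[CVResult], data: pd.DataFrame,
                   predictors, monotone: dict[str, int],
                   hard_bottom: Raster | None = None) -> EnsembleOutput:
    """Median ensemble over refitted members, TSS reclassification and
    optional rocky-bottom interception."""
    if not selected:
        raise ValueError("no selected models")
    models = refit_members(selected, data, monotone)
    by_name = {p.name: p for p in predictors}
    grid = predictors[0].raster.grid

    names, _, rows, cols = stack_predictors(predictors)
    surfaces = []
    record_preds = []
    y = data["y"].to_numpy(dtype=float)
    for res, model in zip(selected, models):
        plist = [by_name[n] for n in res.combination]
        Xcells = np.column_stack([p.raster.values[rows, cols] for p in plist])
        surfaces.append(model.predict(Xcells))
        record_preds.append(
            model.predict(data.loc[:, list(res.combination)].to_numpy(dtype=float)))
    S = np.vstack(surfaces)
    med_cells = np.median(S, axis=0)
    sd_cells = S.std(axis=0, ddof=0)

    med = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    med[rows, cols] = med_cells
    sd[rows, cols] = sd_cells

    p_records = np.median(np.vstack(record_preds), axis=0)
    stats = evaluate_tss(p_records, y)
    binary_vals = np.where(np.isfinite(med),
                           (med >= stats.threshold).astype(float), np.nan)
    binary = Raster(grid, binary_vals)
    binary_rock = (intersect_substrate(binary, hard_bottom)
                   if hard_bottom is not None else None)
    return EnsembleOutput(median=Raster(grid, med), sd=Raster(grid, sd),
                          binary=binary, binary_rock=binary_rock,
                          threshold=stats.threshold, stats=stats,
                          members=models,
                          member_combos=[r.combination for r in selected])


def intersect_substrate(binary: Raster, hard_bottom: Raster) -> Raster:
    """Logical AND with the rocky-bottom mask; cells with missing substrate
    information stay missing (counted separately from absences)."""
    if binary.grid != hard_bottom.grid:
        raise ValueError("binary and substrate rasters on different grids")
    b = binary.values
    r = hard_bottom.values
    out = np.where(np.isfinite(b) & np.isfinite(r), b * (r > 0), np.nan)
    return Raster(binary.grid, out)


def mpa_overlap_pct(binary: Raster, mpas) -> float:
    """Percent of suitable area whose cell centers fall inside any MPA."""
    for k, poly in enumerate(mpas):
        if not poly.is_valid:
            raise ValueError(f"invalid MPA polygon at index {k}")
    rows, cols = np.nonzero(np.nan_to_num(binary.values, nan=0.0) > 0)
    if rows.size == 0:
        return 0.0
    areas = cell_area_km2(binary.grid, rows)
    lons = binary.grid.lons()[cols]
    lats = binary.grid.lats()[rows]
    inside = np.zeros(rows.size, dtype=bool)
    for poly in mpas:
        inside |= shapely.contains_xy(poly, lons, lats)
    return float(100.0 * areas[inside].sum() / areas.sum())


def depth_stratify_pct(binary: Raster, bathymetry: Raster,
                       cutoff: float = 50.0) -> float:
    """Percent of suitable area with bottom depth strictly below `cutoff` m."""
    if binary.grid != bathymetry.grid:
        raise ValueError("rasters on different grids")
    rows, cols = np.nonzero(np.nan_to_num(binary.values, nan=0.0) > 0)
    if rows.size == 0:
        return 0.0
    areas = cell_area_km2(binary.grid, rows)
    deep = bathymetry.values[rows, cols] > cutoff
    return float(100.0 * areas[deep].sum() / areas.sum())


@dataclasses.dataclass
class AreaReport:
    """Habitat area and protection accounting (percentages each against
    their own denominator)."""

    area_env_km2: float
    area_rock_km2: float
    mpa_overlap_env_pct: float
    mpa_overlap_rock_pct: float
    mesophotic_rock_pct: float
    mesophotic_rock_protected_pct: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def area_report(output: EnsembleOutput, bathymetry: Raster, mpas,
                mesophotic_cutoff: float = 50.0) -> AreaReport:
    env = output.binary
    rock = output.binary_rock if output.binary_rock is not None else env
    area_env = total_area_km2(env)
    area_rock = total_area_km2(rock)

    # mesophotic share of the rock-suitable map, and the protected share of it
    deep_pct = depth_stratify_pct(rock, bathymetry, mesophotic_cutoff)
    rows, cols = np.nonzero(np.nan_to_num(rock.values, nan=0.0) > 0)
    deep_protected = 0.0
    if rows.size:
        deep = bathymetry.values[rows, cols] > mesophotic_cutoff
        if deep.any():
            deep_vals = np.full(rock.grid.shape, np.nan)
            deep_vals[rows[deep], cols[deep]] = 1.0
            deep_protected = mpa_overlap_pct(Raster(rock.grid, deep_vals), mpas)
    return AreaReport(
        area_env_km2=area_env,
        area_rock_km2=area_rock,
        mpa_overlap_env_pct=mpa_overlap_pct(env, mpas),
        mpa_overlap_rock_pct=mpa_overlap_pct(rock, mpas),
        mesophotic_rock_pct=deep_pct,
        mesophotic_rock_protected_pct=deep_protected,
    )
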