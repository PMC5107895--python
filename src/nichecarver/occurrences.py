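"""Occurrence-record handling: cleaning, gridding, autocorrelation, thinning.

Occurrence sets are plain pandas DataFrames with columns
``lon, lat, depth_m, label, source`` (label in {"presence", "absence"};
``depth_m`` is reported depth and may be NaN — the analysis trusts grid
bathymetry instead).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .grids import Raster, haversine_km

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["lon", "lat", "depth_m", "label", "source"]


def occurrence_frame(lon, lat, depth_m=None, label="presence",
                     source="unknown") -> pd.DataFrame:
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if depth_m is None:
        depth_m = np.full(lon.size, np.nan)
    return pd.DataFrame({
        "lon": lon, "lat": lat,
        "depth_m": np.broadcast_to(np.asarray(depth_m, dtype=float), lon.shape).copy(),
        "label": np.broadcast_to(np.asarray(label, dtype=object), lon.shape).copy(),
        "source": np.broadcast_to(np.asarray(source, dtype=object), lon.shape).copy(),
    })


def clean_and_grid(occ: pd.DataFrame, bathymetry: Raster,
                   max_depth: float = 200.0,
                   min_depth: float | None = None) -> pd.DataFrame:
    """Drop implausible records and collapse them onto the analysis grid.

    Records falling on land cells, or whose *grid* depth exceeds
    ``max_depth`` (or is shallower than ``min_depth`` when given), are
    removed; surviving records are snapped to cell centers and deduplicated
    to one record per (cell, label).  Reported depth is kept as metadata.
    """
    if occ.empty:
        logger.warning("clean_and_grid: empty occurrence set")
        return occ.copy()
    g = bathymetry.grid
    row, col = g.index_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    off_grid = (row < 0)
    grid_depth = np.full(len(occ), np.nan)
    ok = ~off_grid
    grid_depth[ok] = bathymetry.values[row[ok], col[ok]]
    on_land = ok & ~np.isfinite(grid_depth)
    too_deep = np.isfinite(grid_depth) & (grid_depth > max_depth)
    too_shallow = np.zeros(len(occ), dtype=bool)
    if min_depth is not None:
        too_shallow = np.isfinite(grid_depth) & (grid_depth < min_depth)
    drop = off_grid | on_land | too_deep | too_shallow
    logger.info(
        "clean_and_grid: dropped %d off-grid, %d on land, %d deeper than %g m, "
        "%d shallower records of %d",
        off_grid.sum(), on_land.sum(), too_deep.sum(), too_shallow.sum(), len(occ),
    )
    kept = occ.loc[~drop].copy()
    krow, kcol = row[~drop], col[~drop]
    lons, lats = g.lons(), g.lats()
    kept["lon"] = lons[kcol]
    kept["lat"] = lats[krow]
    kept["_cell"] = krow * g.ncols + kcol
    kept = kept.drop_duplicates(subset=["_cell", "label"], keep="first")
    return kept.drop(columns="_cell").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mantel correlogram


@dataclasses.dataclass
class Correlogram:
    """Distance-class Mantel profile of environmental relatedness."""

    edges_km: np.ndarray          # class edges, length n_classes + 1
    mantel_r: np.ndarray          # per class, NaN where undefined
    p_value: np.ndarray
    n_pairs: np.ndarray

    def autocorrelation_range_km(self, alpha: float = 0.05) -> float:
        """Largest distance up to which r > 0 and p < alpha.

        Returns the upper edge of the last class in the initial run of
        positive significant classes; leading classes with too few pairs to
        be defined are skipped; 0 when the first defined class is already
        non-significant.
        """
        range_km = 0.0
        started = False
        for k in range(self.mantel_r.size):
            if not np.isfinite(self.mantel_r[k]):
                if started:
                    break
                continue
            if self.mantel_r[k] > 0 and self.p_value[k] < alpha:
                range_km = float(self.edges_km[k + 1])
                started = True
            else:
                break
        return range_km

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "d_lo_km": self.edges_km[:-1],
            "d_hi_km": self.edges_km[1:],
            "mantel_r": self.mantel_r,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
        })


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_correlogram(occ: pd.DataFrame, predictors, class_width_km: float = 2.5,
                       max_dist_km: float = 50.0, n_perm: int = 9999,
                       seed: int = 0) -> Correlogram:
    """Multivariate Mantel correlogram of predictor distance vs separation.

    Environmental distance is Euclidean on z-scored predictor values at each
    record's cell; for every contiguous distance class the Mantel statistic
    correlates that distance with class membership, with permutation
    p-values obtained by shuffling record identities (the same permutations
    serve every class).  The statistic's sign is flipped so that positive
    spatial autocorrelation (similar environments at close range) reads as
    positive r, matching the usual correlogram convention.
    """
    if len(occ) < 5:
        raise ValueError("need at least 5 records for a correlogram")
    lon = occ["lon"].to_numpy()
    lat = occ["lat"].to_numpy()
    E = np.column_stack([p.raster.sample(lon, lat) for p in predictors])
    ok = np.all(np.isfinite(E), axis=1)
    if ok.sum() < 5:
        raise ValueError("fewer than 5 records with complete predictor values")
    E, lon, lat = E[ok], lon[ok], lat[ok]
    sd = E.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (E - E.mean(axis=0)) / sd

    n = len(lon)
    geo = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    envd = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    dvec = _condensed(envd)
    gvec = _condensed(geo)

    edges = np.arange(0.0, max_dist_km + class_width_km / 2, class_width_km)
    n_classes = edges.size - 1
    indicators = np.zeros((n_classes, dvec.size))
    n_pairs = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        hit = (gvec >= edges[k]) & (gvec < edges[k + 1])
        indicators[k] = hit
        n_pairs[k] = int(hit.sum())

    valid = n_pairs >= 2
    ic = indicators - indicators.mean(axis=1, keepdims=True)
    ic_norm = np.sqrt((ic ** 2).sum(axis=1))
    ic_norm[ic_norm == 0] = np.nan

    def r_all(dmat_vec: np.ndarray) -> np.ndarray:
        dc = dmat_vec - dmat_vec.mean()
        dn = np.sqrt((dc ** 2).sum())
        if dn == 0:
            return np.full(n_classes, np.nan)
        # negated: within-class distances below average -> positive r
        return -(ic @ dc) / (ic_norm * dn)

    r_obs = r_all(dvec)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count_ge = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dperm = envd[np.ix_(perm, perm)][iu]
        r_p = r_all(dperm)
        count_ge += (np.abs(r_p) >= np.abs(r_obs)) | ~np.isfinite(r_p)
    p = (count_ge + 1) / (n_perm + 1)
    r_obs = np.where(valid, r_obs, np.nan)
    p = np.where(valid, p, np.nan)
    return Correlogram(edges_km=edges, mantel_r=r_obs, p_value=p, n_pairs=n_pairs)


def thin_records(occ: pd.DataFrame, min_dist_km: float, seed: int = 0) -> pd.DataFrame:
    """Greedy spatial thinning: keep a maximal subset with pairwise
    great-circle distance >= min_dist_km.

    Records are visited in a seeded random order and kept when at least
    ``min_dist_km`` away from every record already kept, so every dropped
    record is within the threshold of a kept one.  Thinning an already
    thinned set is a no-op.
    """
    if min_dist_km < 0:
        raise ValueError("min_dist_km must be non-negative")
    if occ.empty or min_dist_km == 0:
        return occ.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(occ))
    lon = occ["lon"].to_numpy()
    lat = occ["lat"].to_numpy()
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if np.all(d >= min_dist_km):
            kept.append(i)
    return occ.iloc[sorted(kept)].reset_index(drop=True)
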