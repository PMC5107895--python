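"""Environmentally-informed, effort-weighted pseudo-absences.

Presence-only data give no true absences; pseudo-absences are drawn from the
environmentally least-suitable cells (Mahalanobis distance to the presence
centroid converted to a chi-square tail probability), structured into
environmentally dissimilar groups by K-means and sampled inside each group
proportionally to the observed sampling effort so that the absences inherit
the survey bias of the presences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import KMeans

from .grids import GeoGrid, Raster, haversine_km
from .occurrences import occurrence_frame
from .predictors import stack_predictors

logger = logging.getLogger(__name__)


def esm_mahalanobis(predictors, presences: pd.DataFrame) -> Raster:
    """Environmental Suitability Map from Mahalanobis distance.

    Predictors are z-scored over sea cells; for every cell, D² is the
    Mahalanobis distance of its predictor vector to the presence mean under
    the presence covariance, and suitability is the upper-tail chi-square
    probability with df = number of predictors.  The presence centroid maps
    to suitability 1; suitability decreases monotonically with D².
    """
    names, X, rows, cols = stack_predictors(predictors)
    p = X.shape[1]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    grid = predictors[0].raster.grid
    prow, pcol = grid.index_of(presences["lon"].to_numpy(),
                               presences["lat"].to_numpy())
    cell_index = {}
    for k, (r, c) in enumerate(zip(rows, cols)):
        cell_index[(r, c)] = k
    pres_idx = [cell_index[(r, c)] for r, c in zip(prow, pcol)
                if (r, c) in cell_index]
    if len(pres_idx) < p + 2:
        raise ValueError(f"need at least {p + 2} presences on valid cells "
                         f"for {p} predictors, got {len(pres_idx)}")
    Zp = Z[pres_idx]
    center = Zp.mean(axis=0)
    cov = np.cov(Zp, rowvar=False)
    cov = np.atleast_2d(cov)
    # ridge regularisation guards near-singular covariances
    cov = cov + 1e-6 * np.mean(np.diag(cov)) * np.eye(p)
    if np.linalg.cond(cov) > 1e12:
        corr = np.corrcoef(Zp, rowvar=False)
        iu = np.triu_indices(p, k=1)
        worst = np.argmax(np.abs(corr[iu]))
        a, b = iu[0][worst], iu[1][worst]
        raise ValueError(
            "singular presence covariance after regularisation; most collinear "
            f"predictors: {names[a]!r} and {names[b]!r}")
    prec = np.linalg.inv(cov)
    diff = Z - center
    d2 = np.einsum("ij,jk,ik->i", diff, prec, diff)
    suit = chi2.sf(d2, df=p)
    out = np.full(grid.shape, np.nan)
    out[rows, cols] = suit
    return Raster(grid, out)


def candidate_pool(esm: Raster, presences: pd.DataFrame,
                   threshold: float = 0.2) -> np.ndarray:
    """(row, col) array of sea cells with suitability <= threshold,
    excluding cells occupied by a presence record."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ok = np.isfinite(esm.values) & (esm.values <= threshold)
    prow, pcol = esm.grid.index_of(presences["lon"].to_numpy(),
                                   presences["lat"].to_numpy())
    for r, c in zip(prow, pcol):
        if r >= 0:
            ok[r, c] = False
    rows, cols = np.nonzero(ok)
    if rows.size == 0:
        raise ValueError(
            f"no candidate cells at ESM threshold {threshold}; "
            "consider a larger threshold")
    return np.column_stack([rows, cols])


def effort_surface(all_records: pd.DataFrame, grid: GeoGrid,
                   bandwidth_km: float) -> Raster:
    """Gaussian kernel density of record locations on the grid (per km²).

    The density integrates (sum x cell area) to the number of records when
    the domain amply contains the kernels.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be positive")
    if len(all_records) == 0:
        raise ValueError("need at least one record")
    lon2d, lat2d = grid.mesh()
    lonf = lon2d.ravel()
    latf = lat2d.ravel()
    dens = np.zeros(lonf.size)
    norm = 1.0 / (2 * np.pi * bandwidth_km ** 2)
    for lon, lat in zip(all_records["lon"].to_numpy(),
                        all_records["lat"].to_numpy()):
        d = haversine_km(lon, lat, lonf, latf)
        dens += norm * np.exp(-0.5 * (d / bandwidth_km) ** 2)
    return Raster(grid, dens.reshape(grid.shape))


def draw_pseudo_absences(pool: np.ndarray, predictors, n_presences: int,
                         effort: Raster, seed: int = 0,
                         max_retries: int = 5) -> pd.DataFrame:
    """One pseudo-absence per K-means cluster of the candidate pool.

    The pool's z-scored predictor vectors are clustered with
    k = n_presences; within each cluster one cell is drawn with probability
    proportional to the effort density (uniform if the cluster's effort is
    all zero), giving a balanced presence/absence design.
    """
    if len(pool) < n_presences:
        raise ValueError(f"pool of {len(pool)} cells cannot supply "
                         f"{n_presences} pseudo-absences")
    grid = predictors[0].raster.grid
    rows, cols = pool[:, 0], pool[:, 1]
    X = np.column_stack([p.raster.values[rows, cols] for p in predictors])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    rng = np.random.default_rng(seed)

    if n_presences == len(pool):
        labels = np.arange(len(pool))
    else:
        labels = None
        for attempt in range(max_retries):
            km = KMeans(n_clusters=n_presences, n_init=10,
                        random_state=int(rng.integers(2 ** 31)))
            cand = km.fit_predict(Z)
            if np.unique(cand).size == n_presences:
                labels = cand
                break
            logger.warning("K-means produced an empty cluster (attempt %d)",
                           attempt + 1)
        if labels is None:
            raise RuntimeError("K-means repeatedly produced empty clusters")

    eff = effort.values[rows, cols]
    eff = np.where(np.isfinite(eff) & (eff > 0), eff, 0.0)
    chosen = []
    for k in np.unique(labels):
        members = np.nonzero(labels == k)[0]
        w = eff[members]
        total = w.sum()
        p = w / total if total > 0 else None
        chosen.append(int(rng.choice(members, p=p)))
    lons = grid.lons()[cols[chosen]]
    lats = grid.lats()[rows[chosen]]
    return occurrence_frame(lons, lats, label="absence", source="pseudo")
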