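"""Seabed environmental predictors from 3-D monthly climatologies.

Each predictor is a long-term monthly extreme evaluated at the seabed: for
every analysis cell whose bottom depth lies in the mesophotic working window
(15-200 m by default), the variable is interpolated trilinearly at
(lon, lat, bottom depth) for every year x month, the monthly extreme is taken
within each year, and extremes are averaged across years.  Minimum-type
predictors carry a +1 monotone sign for downstream model constraints,
maximum-type predictors a -1 sign, and terrain (slope) 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grids import EARTH_RADIUS_KM, GeoGrid, Raster
from .profiles import EnvProfileSet

DEPTH_WINDOW_M = (15.0, 200.0)

_SIGN = {"min": +1, "max": -1, "terrain": 0}


@dataclasses.dataclass
class PredictorRaster:
    """A named predictor surface with its monotone sign.

    monotone_sign is derived from the statistic: minimum-type predictors are
    expected to limit the niche from below (+1), maximum-type from above (-1),
    terrain predictors are unconstrained (0).
    """

    raster: Raster
    name: str
    statistic: str

    def __post_init__(self) -> None:
        if self.statistic not in _SIGN:
            raise ValueError(f"statistic must be one of {sorted(_SIGN)}")

    @property
    def monotone_sign(self) -> int:
        return _SIGN[self.statistic]


# ---------------------------------------------------------------------------
# Trilinear interpolation


def _trilinear_weights(grid: GeoGrid, levels: np.ndarray, lon, lat, depth):
    """Corner indices and weights for trilinear queries.

    Returns (iz0, iy0, ix0, wz, wy, wx, valid): lower-corner indices along
    (depth, lat, lon), the fractional weights toward the upper corner, and a
    mask of queries inside the horizontal hull of cell centers.  Depth is
    clamped to [levels[0], levels[-1]].
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    lons = grid.lons()
    lats = grid.lats()  # descending
    res = grid.resolution

    fx = (lon - lons[0]) / res
    fy = (lats[0] - lat) / res
    valid = (fx >= 0) & (fx <= lons.size - 1) & (fy >= 0) & (fy <= lats.size - 1)
    fx = np.clip(fx, 0, lons.size - 1)
    fy = np.clip(fy, 0, lats.size - 1)
    ix0 = np.minimum(np.floor(fx).astype(int), lons.size - 2) if lons.size > 1 \
        else np.zeros_like(fx, dtype=int)
    iy0 = np.minimum(np.floor(fy).astype(int), lats.size - 2) if lats.size > 1 \
        else np.zeros_like(fy, dtype=int)
    wx = fx - ix0 if lons.size > 1 else np.zeros_like(fx)
    wy = fy - iy0 if lats.size > 1 else np.zeros_like(fy)

    d = np.clip(depth, levels[0], levels[-1])
    iz0 = np.clip(np.searchsorted(levels, d, side="right") - 1, 0,
                  max(levels.size - 2, 0))
    if levels.size > 1:
        wz = (d - levels[iz0]) / (levels[iz0 + 1] - levels[iz0])
    else:
        wz = np.zeros_like(d)
    return iz0, iy0, ix0, wz, wy, wx, valid


def _apply_weights(field3d: np.ndarray, w) -> np.ndarray:
    iz0, iy0, ix0, wz, wy, wx, valid = w
    nz, ny, nx = field3d.shape
    iz1 = np.minimum(iz0 + 1, nz - 1)
    iy1 = np.minimum(iy0 + 1, ny - 1)
    ix1 = np.minimum(ix0 + 1, nx - 1)
    c000 = field3d[iz0, iy0, ix0]
    c001 = field3d[iz0, iy0, ix1]
    c010 = field3d[iz0, iy1, ix0]
    c011 = field3d[iz0, iy1, ix1]
    c100 = field3d[iz1, iy0, ix0]
    c101 = field3d[iz1, iy0, ix1]
    c110 = field3d[iz1, iy1, ix0]
    c111 = field3d[iz1, iy1, ix1]
    out = ((1 - wz) * ((1 - wy) * ((1 - wx) * c000 + wx * c001)
                       + wy * ((1 - wx) * c010 + wx * c011))
           + wz * ((1 - wy) * ((1 - wx) * c100 + wx * c101)
                   + wy * ((1 - wx) * c110 + wx * c111)))
    return np.where(valid, out, np.nan)


def trilinear_interpolate(field3d: np.ndarray, levels, grid: GeoGrid,
                          lon, lat, depth) -> np.ndarray:
    """Trilinear blend of the 8 nodes surrounding each (lon, lat, depth).

    `field3d` has shape (n_levels, nlat, nlon) on `grid` with depth `levels`
    (metres, increasing).  Queries outside the horizontal hull of cell centers
    return NaN; depths outside the level span are clamped to the nearest
    level.  The result always lies within [min, max] of the corner nodes.
    """
    levels = np.asarray(levels, dtype=float)
    w = _trilinear_weights(grid, levels, lon, lat, depth)
    out = _apply_weights(np.asarray(field3d, dtype=float), w)
    if np.isscalar(lon) or np.ndim(lon) == 0:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# Predictor construction


def build_predictor(profiles: EnvProfileSet, bathymetry: Raster, variable: str,
                    statistic: str, depth_window=DEPTH_WINDOW_M) -> PredictorRaster:
    """Long-term average of the monthly extreme at the seabed.

    Cells with bottom depth outside `depth_window` (or on land) are missing.
    """
    if statistic not in ("min", "max"):
        raise ValueError("statistic must be 'min' or 'max'")
    if variable not in profiles.variables:
        raise KeyError(f"unknown variable {variable!r}")
    grid = bathymetry.grid
    depth = bathymetry.values
    window = (np.isfinite(depth) & (depth >= depth_window[0])
              & (depth <= depth_window[1]))
    rows, cols = np.nonzero(window)
    out = np.full(grid.shape, np.nan)
    if rows.size:
        lon2d, lat2d = grid.mesh()
        w = _trilinear_weights(profiles.grid, profiles.depth_levels,
                               lon2d[rows, cols], lat2d[rows, cols],
                               depth[rows, cols])
        n_years = len(profiles.years)
        acc = np.zeros((n_years, rows.size))
        extreme = np.min if statistic == "min" else np.max
        for yi in range(n_years):
            monthly = np.stack([
                _apply_weights(profiles.field(variable, yi, mi), w)
                for mi in range(12)
            ])
            acc[yi] = extreme(monthly, axis=0)
        out[rows, cols] = acc.mean(axis=0)
    name = f"{variable}_{statistic}"
    return PredictorRaster(Raster(grid, out), name, statistic)


def compute_slope(bathymetry: Raster) -> PredictorRaster:
    """Seafloor slope (degrees) by Horn's 3x3 method.

    East-west cell size is scaled by cos(latitude) (metric distances on a
    sphere of R = 6371 km).  Cells with any missing neighbour, and edge
    cells, are missing.  Adding a constant to the bathymetry leaves the
    slope unchanged.
    """
    g = bathymetry.grid
    if g.nrows < 3 or g.ncols < 3:
        raise ValueError("slope needs at least a 3x3 grid")
    z = bathymetry.values
    out = np.full(g.shape, np.nan)

    # 3x3 neighbourhood views of the interior
    nb = {}
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            nb[(dr, dc)] = z[1 + dr:g.nrows - 1 + dr, 1 + dc:g.ncols - 1 + dc]
    ok = np.ones_like(nb[(0, 0)], dtype=bool)
    for v in nb.values():
        ok &= np.isfinite(v)

    cell_m = np.radians(g.resolution) * EARTH_RADIUS_KM * 1000.0
    lat_c = g.lats()[1:-1]
    dx = cell_m * np.cos(np.radians(lat_c))[:, None]
    dy = cell_m

    # Horn weights: depth is positive-down, so convert to elevation (-z);
    # slope magnitude is unaffected by the sign convention.
    e = {k: -v for k, v in nb.items()}
    gx = ((e[(-1, 1)] + 2 * e[(0, 1)] + e[(1, 1)])
          - (e[(-1, -1)] + 2 * e[(0, -1)] + e[(1, -1)])) / (8 * dx)
    gy = ((e[(-1, -1)] + 2 * e[(-1, 0)] + e[(-1, 1)])
          - (e[(1, -1)] + 2 * e[(1, 0)] + e[(1, 1)])) / (8 * dy)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    out[1:-1, 1:-1] = np.where(ok, slope, np.nan)
    return PredictorRaster(Raster(g, out), "slope", "terrain")


def stack_predictors(predictors: list[PredictorRaster]):
    """Design matrix over cells where every predictor is defined.

    Returns (names, X, rows, cols): X has one row per common valid cell.
    """
    if not predictors:
        raise ValueError("no predictors given")
    grid = predictors[0].raster.grid
    mask = np.ones(grid.shape, dtype=bool)
    for p in predictors:
        if p.raster.grid != grid:
            raise ValueError("predictors on different grids")
        mask &= p.raster.mask
    rows, cols = np.nonzero(mask)
    X = np.column_stack([p.raster.values[rows, cols] for p in predictors])
    return [p.name for p in predictors], X, rows, cols


# ---------------------------------------------------------------------------
# Quality control against bottle samples


def quality_control(profiles: EnvProfileSet, bottles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between bottle values and interpolated predictions.

    Each bottle is matched to its own year and month when the year is inside
    the profile span; otherwise to the climatological (across-year mean)
    month.  Variables with fewer than 3 usable pairs, or a zero-variance
    series, are flagged.
    """
    rows = []
    year_index = {y: i for i, y in enumerate(profiles.years)}
    for var, sub in bottles.groupby("variable"):
        if var not in profiles.variables:
            rows.append({"variable": var, "n": 0, "r": np.nan,
                         "flag": "unknown variable"})
            continue
        pred = np.empty(len(sub))
        for i, rec in enumerate(sub.itertuples(index=False)):
            mi = int(rec.month) - 1
            yi = year_index.get(int(rec.year))
            if yi is not None:
                field = profiles.field(var, yi, mi)
            else:
                field = profiles.data[var][:, mi].mean(axis=0)
            pred[i] = trilinear_interpolate(field, profiles.depth_levels,
                                            profiles.grid, rec.lon, rec.lat,
                                            rec.depth_m)
        obs = sub["value"].to_numpy(dtype=float)
        ok = np.isfinite(pred) & np.isfinite(obs)
        n = int(ok.sum())
        if n < 3:
            rows.append({"variable": var, "n": n, "r": np.nan,
                         "flag": "insufficient records"})
        elif np.std(pred[ok]) == 0 or np.std(obs[ok]) == 0:
            rows.append({"variable": var, "n": n, "r": np.nan,
                         "flag": "zero variance"})
        else:
            r = float(np.corrcoef(obs[ok], pred[ok])[0, 1])
            rows.append({"variable": var, "n": n, "r": r, "flag": ""})
    return pd.DataFrame(rows, columns=["variable", "n", "r", "flag"])
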