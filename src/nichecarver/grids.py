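"""Regular lon/lat grids, single-band rasters and spherical geometry helpers.

All grids are axis-aligned WGS84 lon/lat grids with a single resolution in
degrees shared by both axes.  Row 0 is the northernmost row and cell values
refer to cell centers.  Missing cells (land, out-of-window) carry NaN.

Distances are great-circle (haversine) on a sphere of radius 6371 km; cell
areas use the spherical-rectangle formula at the cell-center latitude.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclasses.dataclass(frozen=True)
class GeoGrid:
    """A regular lon/lat grid defined by its north-west corner.

    Parameters
    ----------
    lon0 : float
        Longitude of the western edge of the grid (degrees).
    lat0 : float
        Latitude of the northern edge of the grid (degrees).
    resolution : float
        Cell size in degrees (same for both axes); must be positive.
    nrows, ncols : int
        Grid dimensions.  Row 0 is the northernmost row.
    """

    lon0: float
    lat0: float
    resolution: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length ncols)."""
        return self.lon0 + (np.arange(self.ncols) + 0.5) * self.resolution

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length nrows)."""
        return self.lat0 - (np.arange(self.nrows) + 0.5) * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.lon0 + (col + 0.5) * self.resolution,
            self.lat0 - (row + 0.5) * self.resolution,
        )

    def index_of(self, lon, lat):
        """(row, col) arrays for point coordinates; -1 where off-grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.resolution).astype(int)
        row = np.floor((self.lat0 - lat) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) cell-center coordinate fields of shape (nrows, ncols)."""
        return np.meshgrid(self.lons(), self.lats())

    @classmethod
    def from_extent(cls, lon_min, lon_max, lat_min, lat_max, resolution) -> "GeoGrid":
        ncols = int(round((lon_max - lon_min) / resolution))
        nrows = int(round((lat_max - lat_min) / resolution))
        if ncols < 1 or nrows < 1:
            raise ValueError("degenerate extent: zero cells")
        return cls(lon0=lon_min, lat0=lat_max, resolution=resolution,
                   nrows=nrows, ncols=ncols)


@dataclasses.dataclass
class Raster:
    """One value per grid cell; NaN marks missing (land / outside window)."""

    grid: GeoGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a value."""
        return np.isfinite(self.values)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())

    def sample(self, lon, lat):
        """Nearest-cell lookup at point coordinates; NaN off-grid."""
        row, col = self.grid.index_of(lon, lat)
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = (row >= 0) & (col >= 0)
        out[ok] = self.values[row[ok], col[ok]]
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text single-band raster interchange format)

_NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.lon0!r}\n"
        f"yllcorner {g.lat0 - g.nrows * g.resolution!r}\n"
        f"cellsize {g.resolution!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
    vals = vals.reshape(nrows, ncols)
    nodata = meta.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = GeoGrid(
        lon0=meta["xllcorner"],
        lat0=meta["yllcorner"] + nrows * meta["cellsize"],
        resolution=meta["cellsize"],
        nrows=nrows,
        ncols=ncols,
    )
    return Raster(grid, vals)


# ---------------------------------------------------------------------------
# Spherical geometry


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees.

    Broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def cell_area_km2(grid: GeoGrid, row) -> np.ndarray:
    """Spherical-rectangle area (km^2) of the cells in row `row`.

    area = (R dphi) * (R dlambda cos(phi_center)); constant along a row.
    """
    row = np.asarray(row)
    lat_center = grid.lat0 - (row + 0.5) * grid.resolution
    d = np.radians(grid.resolution) * EARTH_RADIUS_KM
    return d * d * np.cos(np.radians(lat_center))


def total_area_km2(binary: Raster) -> float:
    """Total area of cells that are truthy (non-zero, non-missing)."""
    rows, cols = np.nonzero(np.nan_to_num(binary.values, nan=0.0) > 0)
    if rows.size == 0:
        return 0.0
    return float(np.sum(cell_area_km2(binary.grid, rows)))
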