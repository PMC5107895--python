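"""Monthly 3-D environmental climatologies and bottle (water-sample) data.

An :class:`EnvProfileSet` holds, for each variable, monthly-mean fields on a
(year, month, depth level, lat, lon) lattice.  The horizontal lattice is
usually much coarser than the analysis bathymetry; predictor construction
brings it onto the fine grid by trilinear interpolation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GeoGrid


@dataclasses.dataclass
class EnvProfileSet:
    """variable -> array of shape (n_years, 12, n_levels, nlat, nlon)."""

    grid: GeoGrid
    variables: list[str]
    years: list[int]
    depth_levels: np.ndarray  # metres, strictly increasing
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        if self.depth_levels.size == 0:
            raise ValueError("depth_levels must be non-empty")
        if not np.all(np.diff(self.depth_levels) > 0):
            raise ValueError("depth_levels must be strictly increasing")
        shape = (len(self.years), 12, self.depth_levels.size,
                 self.grid.nrows, self.grid.ncols)
        for var in self.variables:
            if self.data[var].shape != shape:
                raise ValueError(f"{var}: shape {self.data[var].shape} != {shape}")

    def field(self, variable: str, year_idx: int, month_idx: int) -> np.ndarray:
        """(n_levels, nlat, nlon) field for one variable/year/month."""
        if variable not in self.data:
            raise KeyError(f"unknown variable {variable!r}")
        return self.data[variable][year_idx, month_idx]

    def to_xarray(self) -> xr.Dataset:
        coords = {
            "year": self.years,
            "month": np.arange(1, 13),
            "depth": self.depth_levels,
            "lat": self.grid.lats(),
            "lon": self.grid.lons(),
        }
        ds = xr.Dataset(
            {v: (("year", "month", "depth", "lat", "lon"), self.data[v])
             for v in self.variables},
            coords=coords,
        )
        ds.attrs["resolution"] = self.grid.resolution
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "EnvProfileSet":
        res = float(ds.attrs["resolution"])
        lat = ds["lat"].values
        lon = ds["lon"].values
        grid = GeoGrid(lon0=float(lon[0]) - res / 2, lat0=float(lat[0]) + res / 2,
                       resolution=res, nrows=lat.size, ncols=lon.size)
        variables = [str(v) for v in ds.data_vars]
        return cls(
            grid=grid,
            variables=variables,
            years=[int(y) for y in ds["year"].values],
            depth_levels=ds["depth"].values.astype(float),
            data={v: ds[v].values.astype(float) for v in variables},
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "EnvProfileSet":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_xarray(ds.load())


BOTTLE_COLUMNS = ["lon", "lat", "depth_m", "month", "year", "variable", "value"]


def bottle_frame(records=None) -> pd.DataFrame:
    """Normalised bottle-sample table (one row per measurement)."""
    if records is None:
        return pd.DataFrame(columns=BOTTLE_COLUMNS)
    df = pd.DataFrame(records)
    missing = set(BOTTLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bottle data missing columns: {sorted(missing)}")
    return df[BOTTLE_COLUMNS]
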