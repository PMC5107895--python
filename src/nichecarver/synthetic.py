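"""Seeded synthetic worlds with a known true niche.

The generator emulates the statistical structure the downstream analysis
assumes: a coastal bathymetry with a shelf gradient and seamounts, monthly
3-D environmental fields built from latitudinal gradients, seasonal cycles,
vertical lapses and short-range spatial anomalies, presence-only sampling
driven by a known suitability function under spatially biased effort, a
patchy hard-bottom mask, polygonal MPAs and noisy bottle samples.  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from . import predictors as pr
from .grids import GeoGrid, Raster
from .occurrences import occurrence_frame
from .profiles import EnvProfileSet, bottle_frame


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _smooth_field(shape, scale_cells: float, rng) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (correlation ~scale_cells)."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=max(scale_cells, 1e-6), mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# Niche truth


@dataclasses.dataclass(frozen=True)
class PlateauResponse:
    """Suitability response of one predictor: 1 well inside [lo, hi],
    crossing 0.5 exactly at lo and hi, with logistic edges of the given
    softness.  Either bound may be None for an open-ended ramp."""

    lo: float | None = None
    hi: float | None = None
    softness: float = 0.5

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        r = np.ones_like(x)
        if self.lo is not None:
            r = r / (1.0 + np.exp(-(x - self.lo) / self.softness))
        if self.hi is not None:
            r = r / (1.0 + np.exp((x - self.hi) / self.softness))
        return r


@dataclasses.dataclass(frozen=True)
class NicheFunction:
    """Product of per-predictor plateau/ramp responses, in [0, 1]."""

    responses: dict[str, PlateauResponse]

    def suitability(self, values: dict[str, np.ndarray]) -> np.ndarray:
        out = None
        for name, resp in self.responses.items():
            r = resp(values[name])
            out = r if out is None else out * r
        if out is None:
            raise ValueError("niche has no responses")
        return out

    def true_limits(self) -> dict[str, tuple[float | None, float | None]]:
        """The (lo, hi) used to build each response (round-trip)."""
        return {name: (resp.lo, resp.hi) for name, resp in self.responses.items()}

    def suitability_raster(self, predictor_list) -> Raster:
        by_name = {p.name: p for p in predictor_list}
        grid = predictor_list[0].raster.grid
        vals = {n: by_name[n].raster.values for n in self.responses}
        suit = self.suitability(vals)
        mask = np.ones(grid.shape, dtype=bool)
        for n in self.responses:
            mask &= by_name[n].raster.mask
        return Raster(grid, np.where(mask, suit, np.nan))


# ---------------------------------------------------------------------------
# Bathymetry


def generate_bathymetry(extent=(0.0, 16.0, 30.0, 46.0), resolution: float = 0.08,
                        n_seamounts: int = 3, seed: int = 0) -> Raster:
    """Coastal shelf bathymetry: land band along the eastern edge, depth
    increasing smoothly offshore (westward), plus isolated shallow seamounts.

    The shelf slope scales with the extent so the mesophotic window spans
    most of the sea regardless of domain size.  With ``n_seamounts=0`` depth
    is monotone along every shore-normal (east-west) transect.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    width = lon_max - lon_min
    grid = GeoGrid.from_extent(lon_min, lon_max, lat_min, lat_max, resolution)
    lon2d, lat2d = grid.mesh()
    rng = np.random.default_rng(seed)

    # coastline longitude as a smooth function of latitude
    t = (lat2d - lat_min) / max(lat_max - lat_min, 1e-9)
    coast = (lon_max - 0.08 * width
             + 0.03 * width * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi)))
    slope_m_per_deg = 200.0 / width  # ~200 m across the full offshore span
    curv = 0.5 * (8.0 / width) ** 2

    def shelf(d):
        return 12.0 + slope_m_per_deg * d + curv * d ** 2

    dist = coast - lon2d  # degrees offshore
    depth = shelf(dist)
    depth[dist <= 0] = np.nan  # land band

    for _ in range(n_seamounts):
        # seamounts sit offshore, rising to a shallow top
        clon = rng.uniform(lon_min + 0.1 * width, lon_min + 0.6 * width)
        clat = rng.uniform(lat_min + 0.1 * (lat_max - lat_min),
                           lat_max - 0.1 * (lat_max - lat_min))
        sigma = rng.uniform(0.02, 0.04) * width
        top = rng.uniform(25.0, 60.0)
        r2 = (lon2d - clon) ** 2 + (lat2d - clat) ** 2
        bump = np.exp(-r2 / (2 * sigma ** 2))
        h = np.maximum(shelf(coast - clon) - top, 0.0)
        depth = np.where(np.isfinite(depth), np.maximum(depth - h * bump, top), depth)
    return Raster(grid, depth)


# ---------------------------------------------------------------------------
# Environmental profiles


@dataclasses.dataclass(frozen=True)
class VarParams:
    """Structure of one synthetic variable (units are the variable's own).

    base: domain-wide mean at the southern edge and the shallowest level.
    lat_gradient: change per degree of latitude northward.
    seasonal_amp: mean seasonal semi-amplitude at the surface.
    seasonal_amp_var: spatial modulation of the semi-amplitude.
    seasonal_phase: month (1-12) at which the seasonal maximum occurs.
    depth_delta: total change from the first to the last depth level.
    anomaly_sd / anomaly_scale_deg: short-range spatial anomaly field.
    interannual_sd: sd of the per-year offset.
    clip_min: physical lower bound (e.g. concentrations >= 0).
    """

    base: float
    lat_gradient: float
    seasonal_amp: float
    seasonal_amp_var: float = 0.0
    seasonal_phase: float = 8.0
    depth_delta: float = 0.0
    anomaly_sd: float = 0.0
    anomaly_scale_deg: float = 0.1
    interannual_sd: float = 0.0
    clip_min: float | None = None


def default_env_params() -> dict[str, VarParams]:
    """Study-condition defaults: a temperate shelf sea, four variables."""
    return {
        "temperature": VarParams(base=24.0, lat_gradient=-0.45, seasonal_amp=3.5,
                                 seasonal_amp_var=2.8, seasonal_phase=8.0,
                                 depth_delta=-5.0, anomaly_sd=2.5,
                                 anomaly_scale_deg=0.1, interannual_sd=0.3),
        "salinity": VarParams(base=36.5, lat_gradient=0.05, seasonal_amp=0.2,
                              seasonal_amp_var=0.05, seasonal_phase=2.0,
                              depth_delta=1.0, anomaly_sd=0.5,
                              anomaly_scale_deg=0.15, interannual_sd=0.05),
        "nitrate": VarParams(base=1.5, lat_gradient=0.08, seasonal_amp=0.6,
                             seasonal_amp_var=0.2, seasonal_phase=2.0,
                             depth_delta=3.0, anomaly_sd=0.8,
                             anomaly_scale_deg=0.12, interannual_sd=0.1,
                             clip_min=0.05),
        "npp": VarParams(base=350.0, lat_gradient=4.0, seasonal_amp=120.0,
                         seasonal_amp_var=30.0, seasonal_phase=4.0,
                         depth_delta=-250.0, anomaly_sd=80.0,
                         anomaly_scale_deg=0.08, interannual_sd=10.0,
                         clip_min=5.0),
    }


DEFAULT_DEPTH_LEVELS = np.array([10.0, 20.0, 40.0, 70.0, 100.0, 140.0, 180.0, 220.0])


def generate_env_profiles(bathymetry: Raster,
                          years=tuple(range(2000, 2011)),
                          depth_levels=DEFAULT_DEPTH_LEVELS,
                          params: dict[str, VarParams] | None = None,
                          seed: int = 0,
                          coarse_resolution: float = 0.25) -> EnvProfileSet:
    """Monthly 3-D fields on a coarse lattice padded around the bathymetry.

    Each variable = latitudinal gradient + spatially-modulated seasonal
    sinusoid (damped with depth) + vertical lapse + smooth spatial anomaly
    + per-year interannual offset.
    """
    depth_levels = np.asarray(depth_levels, dtype=float)
    if depth_levels.size == 0:
        raise ValueError("depth_levels must be non-empty")
    if params is None:
        params = default_env_params()
    g = bathymetry.grid
    pad = coarse_resolution
    cg = GeoGrid.from_extent(
        g.lon0 - pad, g.lon0 + g.ncols * g.resolution + pad,
        g.lat0 - g.nrows * g.resolution - pad, g.lat0 + pad,
        coarse_resolution,
    )
    lon2d, lat2d = cg.mesh()
    lat_min = lat2d.min()
    z0, zN = depth_levels[0], depth_levels[-1]
    zfrac = ((depth_levels - z0) / (zN - z0) if zN > z0
             else np.zeros_like(depth_levels))
    damp = np.exp(-(depth_levels - z0) / 350.0)
    months = np.arange(1, 13)

    variables = list(params)
    seeds = _child_seeds(seed, len(variables))
    data = {}
    scale_cells = 1.0 / coarse_resolution
    for var, vseed in zip(variables, seeds):
        p = params[var]
        rng = np.random.default_rng(vseed)
        amp = p.seasonal_amp + p.seasonal_amp_var * _smooth_field(
            cg.shape, 1.5 / coarse_resolution, rng)
        amp = np.maximum(amp, 0.0)
        anomaly = p.anomaly_sd * _smooth_field(
            cg.shape, max(p.anomaly_scale_deg, coarse_resolution) * scale_cells, rng)
        yearly = rng.normal(0.0, p.interannual_sd, size=len(years)) \
            if p.interannual_sd > 0 else np.zeros(len(years))
        base2d = p.base + p.lat_gradient * (lat2d - lat_min) + anomaly
        season = np.cos(2 * np.pi * (months - p.seasonal_phase) / 12.0)
        arr = np.empty((len(years), 12, depth_levels.size, cg.nrows, cg.ncols))
        for li, (zf, dmp) in enumerate(zip(zfrac, damp)):
            level2d = base2d + p.depth_delta * zf
            for mi, s in enumerate(season):
                field = level2d + amp * dmp * s
                arr[:, mi, li] = field[None, :, :] + yearly[:, None, None]
        if p.clip_min is not None:
            np.clip(arr, p.clip_min, None, out=arr)
        data[var] = arr
    return EnvProfileSet(grid=cg, variables=variables, years=list(years),
                         depth_levels=depth_levels, data=data)


# ---------------------------------------------------------------------------
# Presence sampling, substrate, MPAs, bottles


def sample_presences(suitability: Raster, n: int, effort_bias: Raster,
                     seed: int = 0):
    """Draw n presence cells without replacement, P(cell) ∝ suitability x effort."""
    suit = suitability.values
    eff = effort_bias.values
    if np.nanmin(eff) < 0:
        raise ValueError("effort_bias must be non-negative")
    w = np.where(np.isfinite(suit) & np.isfinite(eff), suit * eff, 0.0)
    w = np.clip(w, 0.0, None)
    flat = w.ravel()
    positive = int((flat > 0).sum())
    if n > positive:
        raise ValueError(f"only {positive} cells with positive probability, "
                         f"cannot draw {n}")
    if n == 0:
        return occurrence_frame([], [], label="presence", source="synthetic")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, w.shape)
    lons = suitability.grid.lons()[cols]
    lats = suitability.grid.lats()[rows]
    return occurrence_frame(lons, lats, label="presence", source="synthetic")


def generate_hard_bottom(grid: GeoGrid, fraction: float = 0.4,
                         patch_scale: float = 0.2, seed: int = 0,
                         sea_mask: np.ndarray | None = None) -> Raster:
    """Patchy boolean rocky-substrate mask with ≈fraction of sea cells rocky."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    field = _smooth_field(grid.shape, patch_scale / grid.resolution, rng)
    if sea_mask is None:
        sea_mask = np.ones(grid.shape, dtype=bool)
    vals = np.full(grid.shape, np.nan)
    sea_vals = field[sea_mask]
    if fraction == 0.0:
        vals[sea_mask] = 0.0
    elif fraction == 1.0:
        vals[sea_mask] = 1.0
    else:
        thr = np.quantile(sea_vals, 1.0 - fraction)
        vals[sea_mask] = (sea_vals > thr).astype(float)
    return Raster(grid, vals)


def generate_mpas(extent=(0.0, 16.0, 30.0, 46.0), n: int = 5,
                  seed: int = 0) -> list[Polygon]:
    """n non-empty, valid polygons inside the extent (jittered star-convex)."""
    lon_min, lon_max, lat_min, lat_max = extent
    rng = np.random.default_rng(seed)
    domain = box(lon_min, lat_min, lon_max, lat_max)
    polys: list[Polygon] = []
    while len(polys) < n:
        clon = rng.uniform(lon_min, lon_max)
        clat = rng.uniform(lat_min, lat_max)
        base_r = rng.uniform(0.15, 0.5)
        ang = np.linspace(0, 2 * np.pi, 13)[:-1]
        radii = base_r * rng.uniform(0.6, 1.4, size=ang.size)
        ring = [(clon + r * np.cos(a), clat + r * np.sin(a))
                for r, a in zip(radii, ang)]
        poly = Polygon(ring).buffer(0).intersection(domain)
        if poly.is_valid and not poly.is_empty and poly.geom_type == "Polygon":
            polys.append(poly)
    return polys


def generate_bottle_samples(profiles: EnvProfileSet, n: int = 300,
                            noise_sd: float | dict = 0.0, seed: int = 0):
    """n water samples drawn from the profile fields plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    lons = profiles.grid.lons()
    lats = profiles.grid.lats()
    recs = []
    for _ in range(n):
        var = profiles.variables[rng.integers(len(profiles.variables))]
        yi = int(rng.integers(len(profiles.years)))
        mi = int(rng.integers(12))
        lon = rng.uniform(lons[0], lons[-1])
        lat = rng.uniform(lats[-1], lats[0])
        depth = rng.uniform(profiles.depth_levels[0], profiles.depth_levels[-1])
        value = pr.trilinear_interpolate(profiles.field(var, yi, mi),
                                         profiles.depth_levels, profiles.grid,
                                         lon, lat, depth)
        sd = noise_sd.get(var, 0.0) if isinstance(noise_sd, dict) else noise_sd
        if sd > 0:
            value += rng.normal(0.0, sd)
        recs.append({"lon": lon, "lat": lat, "depth_m": depth,
                     "month": mi + 1, "year": profiles.years[yi],
                     "variable": var, "value": value})
    return bottle_frame(recs)


# ---------------------------------------------------------------------------
# Whole worlds


@dataclasses.dataclass
class SyntheticWorld:
    """A complete seeded study system with known truth."""

    grid: GeoGrid
    bathymetry: Raster
    profiles: EnvProfileSet
    predictors: list  # of PredictorRaster
    true_niche: NicheFunction
    suitability: Raster
    presences: object  # occurrence DataFrame
    effort_bias: Raster
    hard_bottom: Raster
    mpas: list[Polygon]
    seed: int


DEFAULT_NICHE = NicheFunction(responses={
    "temperature_min": PlateauResponse(lo=14.0, hi=None, softness=0.15),
    "temperature_max": PlateauResponse(lo=None, hi=24.0, softness=0.15),
})


def generate_world(seed: int = 0, extent=(0.0, 16.0, 30.0, 46.0),
                   resolution: float = 0.08, n_presences: int = 150,
                   n_seamounts: int = 3, niche: NicheFunction = DEFAULT_NICHE,
                   effort_west_bias: float = 3.0,
                   depth_window=pr.DEPTH_WINDOW_M) -> SyntheticWorld:
    """The default study system: 200x200 grid, six predictors, a thermal
    plateau niche of [14, 24] °C, and west-biased sampling effort."""
    s_bathy, s_prof, s_pres, s_rock, s_mpa = _child_seeds(seed, 5)
    bathy = generate_bathymetry(extent, resolution, n_seamounts, s_bathy)
    profiles = generate_env_profiles(bathy, seed=s_prof)
    plist = [
        pr.build_predictor(profiles, bathy, "temperature", "min", depth_window),
        pr.build_predictor(profiles, bathy, "temperature", "max", depth_window),
        pr.build_predictor(profiles, bathy, "salinity", "min", depth_window),
        pr.build_predictor(profiles, bathy, "nitrate", "max", depth_window),
        pr.build_predictor(profiles, bathy, "npp", "min", depth_window),
        pr.compute_slope(bathy),
    ]
    suit = niche.suitability_raster(plist)
    lon2d, _ = bathy.grid.mesh()
    lon_mid = (extent[0] + extent[1]) / 2
    eff = np.where(lon2d < lon_mid, effort_west_bias, 1.0)
    effort = Raster(bathy.grid, eff)
    presences = sample_presences(suit, n_presences, effort, s_pres)
    rock = generate_hard_bottom(bathy.grid, fraction=0.4, patch_scale=0.2,
                                seed=s_rock, sea_mask=bathy.mask)
    mpas = generate_mpas(extent, n=5, seed=s_mpa)
    return SyntheticWorld(grid=bathy.grid, bathymetry=bathy, profiles=profiles,
                          predictors=plist, true_niche=niche, suitability=suit,
                          presences=presences, effort_bias=effort,
                          hard_bottom=rock, mpas=mpas, seed=seed)
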