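import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RegularGridInterpolator

from nichecarver.grids import GeoGrid, Raster
from nichecarver.predictors import (build_predictor, compute_slope,
                                    quality_control, trilinear_interpolate)
from nichecarver.profiles import EnvProfileSet, bottle_frame


def coarse_grid():
    return GeoGrid(lon0=0.0, lat0=4.0, resolution=0.5, nrows=8, ncols=8)


LEVELS = np.array([10.0, 50.0, 100.0, 200.0])


class TestTrilinear:
    def test_constant_field(self):
        g = coarse_grid()
        f = np.full((4, 8, 8), 3.7)
        assert trilinear_interpolate(f, LEVELS, g, 1.3, 2.2, 77.0) == \
            pytest.approx(3.7)

    def test_exact_at_node(self):
        g = coarse_grid()
        rng = np.random.default_rng(0)
        f = rng.normal(size=(4, 8, 8))
        # node (level 2, row 3, col 5)
        lon = g.lons()[5]
        lat = g.lats()[3]
        assert trilinear_interpolate(f, LEVELS, g, lon, lat, LEVELS[2]) == \
            pytest.approx(f[2, 3, 5], rel=1e-12)

    def test_linear_field_reproduced_exactly(self):
        g = coarse_grid()
        lon2d, lat2d = g.mesh()
        f = np.stack([2.0 * lon2d + 3.0 * lat2d - 0.01 * z for z in LEVELS])
        rng = np.random.default_rng(1)
        for _ in range(20):
            lon = rng.uniform(g.lons()[0], g.lons()[-1])
            lat = rng.uniform(g.lats()[-1], g.lats()[0])
            depth = rng.uniform(LEVELS[0], LEVELS[-1])
            expect = 2.0 * lon + 3.0 * lat - 0.01 * depth
            assert trilinear_interpolate(f, LEVELS, g, lon, lat, depth) == \
                pytest.approx(expect, rel=1e-10)

    def test_outside_horizontal_hull_missing(self):
        g = coarse_grid()
        f = np.ones((4, 8, 8))
        assert np.isnan(trilinear_interpolate(f, LEVELS, g, 99.0, 2.0, 50.0))

    def test_depth_clamped_to_levels(self):
        g = coarse_grid()
        f = np.stack([np.full((8, 8), v) for v in (1.0, 2.0, 3.0, 4.0)])
        assert trilinear_interpolate(f, LEVELS, g, 1.0, 2.0, 5.0) == \
            pytest.approx(1.0)
        assert trilinear_interpolate(f, LEVELS, g, 1.0, 2.0, 500.0) == \
            pytest.approx(4.0)

    def test_matches_scipy_regular_grid_interpolator(self):
        g = coarse_grid()
        rng = np.random.default_rng(2)
        f = rng.normal(size=(4, 8, 8))
        # scipy wants ascending axes; our lat axis descends
        rgi = RegularGridInterpolator((LEVELS, g.lats()[::-1], g.lons()),
                                      f[:, ::-1, :])
        for _ in range(30):
            lon = rng.uniform(g.lons()[0], g.lons()[-1])
            lat = rng.uniform(g.lats()[-1], g.lats()[0])
            depth = rng.uniform(LEVELS[0], LEVELS[-1])
            mine = trilinear_interpolate(f, LEVELS, g, lon, lat, depth)
            ref = float(rgi([depth, lat, lon])[0])
            assert mine == pytest.approx(ref, rel=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_bounded_by_corner_values(self, data):
        g = coarse_grid()
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        f = rng.normal(size=(4, 8, 8))
        lon = data.draw(st.floats(0.25, 3.75))
        lat = data.draw(st.floats(0.25, 3.75))
        depth = data.draw(st.floats(10.0, 200.0))
        v = trilinear_interpolate(f, LEVELS, g, lon, lat, depth)
        assert f.min() - 1e-12 <= v <= f.max() + 1e-12


def make_profiles(monthly_values, years=(2000,), grid=None):
    """Single-variable profile set with each month set to a constant."""
    g = grid or coarse_grid()
    arr = np.empty((len(years), 12, LEVELS.size, g.nrows, g.ncols))
    for yi in range(len(years)):
        for mi in range(12):
            arr[yi, mi] = monthly_values[yi][mi]
    return EnvProfileSet(grid=g, variables=["temperature"], years=list(years),
                         depth_levels=LEVELS, data={"temperature": arr})


def shelf_bathymetry():
    g = GeoGrid(lon0=0.5, lat0=3.5, resolution=0.25, nrows=8, ncols=8)
    depth = np.full(g.shape, 100.0)
    depth[0, :] = 300.0   # too deep -> outside the working window
    depth[1, :] = np.nan  # land
    return Raster(g, depth)


class TestBuildPredictor:
    def test_time_invariant_min_equals_max(self):
        prof = make_profiles([[5.0] * 12])
        bathy = shelf_bathymetry()
        lo = build_predictor(prof, bathy, "temperature", "min")
        hi = build_predictor(prof, bathy, "temperature", "max")
        np.testing.assert_allclose(lo.raster.values, hi.raster.values)
        assert lo.monotone_sign == +1 and hi.monotone_sign == -1

    def test_seasonal_cycle_extremes(self):
        months = [15.0 + 5.0 * np.sin(2 * np.pi * m / 12) for m in range(1, 13)]
        prof = make_profiles([months, months])  # two identical years
        bathy = shelf_bathymetry()
        hi = build_predictor(prof, bathy, "temperature", "max")
        lo = build_predictor(prof, bathy, "temperature", "min")
        sea = np.isfinite(hi.raster.values)
        assert hi.raster.values[sea] == pytest.approx(max(months), rel=1e-9)
        assert lo.raster.values[sea] == pytest.approx(min(months), rel=1e-9)

    def test_min_not_above_max_on_noisy_years(self):
        rng = np.random.default_rng(3)
        years = [list(rng.normal(15, 3, 12)) for _ in range(5)]
        prof = make_profiles(years, years=tuple(range(2000, 2005)))
        bathy = shelf_bathymetry()
        lo = build_predictor(prof, bathy, "temperature", "min").raster.values
        hi = build_predictor(prof, bathy, "temperature", "max").raster.values
        sea = np.isfinite(lo)
        assert np.all(lo[sea] <= hi[sea] + 1e-12)

    def test_cells_outside_depth_window_missing(self):
        prof = make_profiles([[5.0] * 12])
        bathy = shelf_bathymetry()
        p = build_predictor(prof, bathy, "temperature", "min")
        assert np.all(np.isnan(p.raster.values[0, :]))  # 300 m deep
        assert np.all(np.isnan(p.raster.values[1, :]))  # land

    def test_unknown_variable_error(self):
        prof = make_profiles([[5.0] * 12])
        with pytest.raises(KeyError):
            build_predictor(prof, shelf_bathymetry(), "oxygen", "min")


class TestSlope:
    def grid(self):
        return GeoGrid(lon0=0.0, lat0=0.02, resolution=0.001, nrows=20,
                       ncols=20)

    def test_flat_is_zero(self):
        g = self.grid()
        s = compute_slope(Raster(g, np.full(g.shape, 50.0)))
        interior = s.raster.values[1:-1, 1:-1]
        assert np.allclose(interior, 0.0)
        assert np.all(np.isnan(s.raster.values[0, :]))  # edge policy

    def test_plane_rising_north(self):
        g = self.grid()
        # 0.1 m rise per metre northward
        cell_m = np.radians(g.resolution) * 6371e3
        _, lat2d = g.mesh()
        row_idx = np.arange(g.nrows)[:, None] * np.ones((1, g.ncols))
        depth = 1000.0 + 0.1 * cell_m * row_idx  # deeper southward
        s = compute_slope(Raster(g, depth))
        interior = s.raster.values[1:-1, 1:-1]
        assert np.nanmean(interior) == pytest.approx(np.degrees(np.arctan(0.1)),
                                                     rel=1e-3)

    def test_east_west_plane_same_magnitude(self):
        g = self.grid()
        cell_m = np.radians(g.resolution) * 6371e3
        lat_c = np.cos(np.radians(g.lats().mean()))
        col_idx = np.ones((g.nrows, 1)) * np.arange(g.ncols)[None, :]
        depth = 1000.0 + 0.1 * cell_m * lat_c * col_idx
        s = compute_slope(Raster(g, depth))
        interior = s.raster.values[1:-1, 1:-1]
        assert np.nanmean(interior) == pytest.approx(np.degrees(np.arctan(0.1)),
                                                     rel=1e-2)

    def test_invariant_under_constant_offset(self):
        g = self.grid()
        rng = np.random.default_rng(4)
        z = rng.uniform(50, 150, g.shape)
        s1 = compute_slope(Raster(g, z)).raster.values
        s2 = compute_slope(Raster(g, z + 500.0)).raster.values
        np.testing.assert_allclose(s1, s2, rtol=1e-10)

    def test_all_missing_in_gives_all_missing_out(self):
        g = self.grid()
        s = compute_slope(Raster(g, np.full(g.shape, np.nan)))
        assert np.all(np.isnan(s.raster.values))


class TestQualityControl:
    def _profiles(self):
        g = coarse_grid()
        lon2d, lat2d = g.mesh()
        arr = np.empty((2, 12, LEVELS.size, g.nrows, g.ncols))
        for yi in range(2):
            for mi in range(12):
                for li, z in enumerate(LEVELS):
                    arr[yi, mi, li] = (10 + lon2d + 0.5 * lat2d - 0.01 * z
                                       + 0.3 * mi + 0.5 * yi)
        return EnvProfileSet(grid=g, variables=["temperature"],
                             years=[2000, 2001], depth_levels=LEVELS,
                             data={"temperature": arr})

    def _bottles(self, profiles, n, transform, seed=0):
        from nichecarver.synthetic import generate_bottle_samples

        b = generate_bottle_samples(profiles, n=n, noise_sd=0.0, seed=seed)
        b["value"] = transform(b["value"].to_numpy(),
                               np.random.default_rng(seed + 1))
        return b

    def test_exact_bottles_perfect_correlation(self):
        prof = self._profiles()
        b = self._bottles(prof, 50, lambda v, rng: v)
        qc = quality_control(prof, b)
        assert qc.loc[0, "r"] == pytest.approx(1.0, abs=1e-9)
        assert qc.loc[0, "n"] == 50

    def test_negated_bottles_anticorrelated(self):
        prof = self._profiles()
        b = self._bottles(prof, 50, lambda v, rng: -v)
        qc = quality_control(prof, b)
        assert qc.loc[0, "r"] == pytest.approx(-1.0, abs=1e-9)

    def test_noise_attenuates_r_to_known_level(self):
        # signal:noise variance 1:1 -> r ~ 1/sqrt(2)
        prof = self._profiles()
        b = self._bottles(
            prof, 2000,
            lambda v, rng: v + rng.normal(0, v.std(), v.size), seed=2)
        qc = quality_control(prof, b)
        assert qc.loc[0, "r"] == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_zero_variance_flagged(self):
        prof = self._profiles()
        b = self._bottles(prof, 10, lambda v, rng: np.full(v.size, 5.0))
        qc = quality_control(prof, b)
        assert qc.loc[0, "flag"] == "zero variance"
        assert np.isnan(qc.loc[0, "r"])

    def test_too_few_records_flagged(self):
        prof = self._profiles()
        b = self._bottles(prof, 2, lambda v, rng: v)
        qc = quality_control(prof, b)
        assert qc.loc[0, "flag"] == "insufficient records"
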