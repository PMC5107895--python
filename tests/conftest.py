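import numpy as np
import pytest

from nichecarver.grids import GeoGrid, Raster
from nichecarver.predictors import PredictorRaster


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world shared by read-only tests."""
    from nichecarver.synthetic import generate_world

    return generate_world(seed=42, extent=(0.0, 4.0, 38.0, 42.0),
                          resolution=0.08, n_presences=60, n_seamounts=1)


@pytest.fixture()
def flat_grid():
    return GeoGrid(lon0=0.0, lat0=1.0, resolution=0.1, nrows=10, ncols=10)


def make_predictor(grid, values, name="p", statistic="min"):
    return PredictorRaster(Raster(grid, np.asarray(values, dtype=float)),
                           name, statistic)


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory):
    """Three complete end-to-end pipeline runs on the default synthetic
    world, shared by the acceptance tests (niche recovery, ensemble
    fidelity and the monotone audit all interrogate the same runs)."""
    from nichecarver.config import fast_profile
    from nichecarver.pipeline import run

    runs = []
    for seed in (101, 202, 303):
        out = tmp_path_factory.mktemp(f"run_seed{seed}")
        cfg = fast_profile(seed=seed, out_dir=out, tc_max=None)
        run("all", cfg)
        runs.append((seed, out))
    return runs
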