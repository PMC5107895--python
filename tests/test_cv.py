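import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal

from nichecarver.brt import BRTParams
from nichecarver.cv import (CVResult, correlation_filter, evaluate_tss,
                            make_longitudinal_folds, predictor_contribution,
                            select_models, tune_and_cross_validate)
from nichecarver.grids import GeoGrid
from tests.conftest import make_predictor


def correlated_predictors(R, n=4000, seed=0):
    """Rasters whose pairwise correlations follow the target matrix R."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    X = rng.normal(size=(n, R.shape[0])) @ L.T
    side = int(np.sqrt(n))
    g = GeoGrid(lon0=0.0, lat0=side * 0.1, resolution=0.1,
                nrows=side, ncols=side)
    return [make_predictor(g, X[: side * side, j].reshape(side, side),
                           f"p{j}", "min") for j in range(R.shape[0])]


class TestCorrelationFilter:
    def test_duplicated_predictor_never_co_occurs(self):
        R = np.eye(3)
        preds = correlated_predictors(R)
        dup = preds + [make_predictor(preds[0].raster.grid,
                                      preds[0].raster.values.copy(),
                                      "p0_copy", "min")]
        combos = correlation_filter(dup, r_max=0.8, min_size=2)
        for c in combos:
            assert not ({"p0", "p0_copy"} <= set(c))

    def test_independent_predictors_full_set_admissible(self):
        preds = correlated_predictors(np.eye(4))
        combos = correlation_filter(preds, r_max=0.8, min_size=2)
        assert tuple(p.name for p in preds) in combos

    def test_matches_brute_force_enumeration(self):
        R = np.array([
            [1.0, 0.9, 0.1, 0.0, 0.3],
            [0.9, 1.0, 0.2, 0.1, 0.2],
            [0.1, 0.2, 1.0, 0.85, 0.0],
            [0.0, 0.1, 0.85, 1.0, 0.1],
            [0.3, 0.2, 0.0, 0.1, 1.0],
        ])
        preds = correlated_predictors(R, n=40000, seed=1)
        combos = set(correlation_filter(preds, r_max=0.8, min_size=2))
        # oracle: recompute empirical correlations, enumerate all 2^5 subsets
        vals = [p.raster.values.ravel() for p in preds]
        emp = np.corrcoef(np.vstack(vals))
        expect = set()
        names = [p.name for p in preds]
        for size in range(2, 6):
            for sub in itertools.combinations(range(5), size):
                if all(abs(emp[a, b]) < 0.8
                       for a, b in itertools.combinations(sub, 2)):
                    expect.add(tuple(names[k] for k in sub))
        assert combos == expect

    def test_cap_returns_seeded_sample(self):
        preds = correlated_predictors(np.eye(6))
        a = correlation_filter(preds, max_combinations=10, seed=3)
        b = correlation_filter(preds, max_combinations=10, seed=3)
        assert len(a) == 10 and a == b

    def test_no_admissible_combination_error(self):
        R = np.full((3, 3), 0.95)
        np.fill_diagonal(R, 1.0)
        preds = correlated_predictors(R + 1e-6 * np.eye(3), n=40000, seed=2)
        with pytest.raises(ValueError, match="admissible"):
            correlation_filter(preds, r_max=0.8, min_size=2)


class TestFolds:
    def test_ten_records_one_per_band(self):
        fa = make_longitudinal_folds(np.arange(10.0), n_folds=10)
        assert sorted(fa.fold) == list(range(10))

    def test_clustered_records_still_equal_counts(self):
        lon = np.concatenate([np.full(30, 7.0) + np.arange(30) * 1e-4,
                              np.full(10, 7.5) + np.arange(10) * 1e-4])
        fa = make_longitudinal_folds(lon, n_folds=10)
        counts = np.bincount(fa.fold)
        assert counts.max() - counts.min() <= 1

    @settings(deadline=None, max_examples=30)
    @given(n=st.integers(12, 200), seed=st.integers(0, 999))
    def test_band_populations_differ_by_at_most_one(self, n, seed):
        lon = np.random.default_rng(seed).uniform(-10, 10, n)
        fa = make_longitudinal_folds(lon, n_folds=10)
        counts = np.bincount(fa.fold, minlength=10)
        assert counts.max() - counts.min() <= 1
        # bands are ordered by longitude
        means = [lon[fa.fold == k].mean() for k in range(10)]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_too_few_records_or_folds_error(self):
        with pytest.raises(ValueError):
            make_longitudinal_folds(np.arange(5.0), n_folds=10)
        with pytest.raises(ValueError):
            make_longitudinal_folds(np.arange(5.0), n_folds=1)


class TestEvaluateTSS:
    def test_published_sensitivity_specificity_example(self):
        # sensitivity 0.96 and specificity 0.94 combine to TSS 0.90
        pos = np.concatenate([np.full(48, 0.8), np.full(2, 0.1)])
        neg = np.concatenate([np.full(47, 0.2), np.full(3, 0.9)])
        p = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        stats = evaluate_tss(p, y)
        assert stats.sensitivity == pytest.approx(0.96)
        assert stats.specificity == pytest.approx(0.94)
        assert stats.tss == pytest.approx(0.90)

    def test_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        stats = evaluate_tss(p, y)
        assert stats.tss == pytest.approx(1.0)
        assert 0.2 < stats.threshold <= 0.8

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_threshold_search(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=10).round(2)
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        stats = evaluate_tss(p, y)
        best = -np.inf
        for t in np.unique(np.concatenate([p, p - 1e-9, p + 1e-9, [1.1]])):
            pred = p >= t
            sens = (pred & (y == 1)).sum() / 5
            spec = (~pred & (y == 0)).sum() / 5
            best = max(best, sens + spec - 1)
        assert stats.tss == pytest.approx(best, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            evaluate_tss(np.array([0.5, 0.6]), np.array([1.0, 1.0]))

    def test_random_predictions_have_near_zero_expected_tss(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(50):
            p = rng.uniform(size=200)
            y = (rng.uniform(size=200) < 0.5).astype(float)
            vals.append(evaluate_tss(p, y).tss)
        # optimistic bias from threshold optimization is bounded
        assert abs(np.mean(vals)) < 0.1


def toy_cv_data(n=120, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    lon = rng.uniform(0, 10, n)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    if signal:
        y = (x1 + 0.3 * rng.normal(size=n) > 0).astype(float)
    else:
        y = (rng.uniform(size=n) < 0.5).astype(float)
    return pd.DataFrame({"lon": lon, "y": y, "a": x1, "b": x2})


class TestTuneAndCrossValidate:
    def test_deterministic(self):
        data = toy_cv_data()
        kw = dict(monotone={"a": 0, "b": 0}, lr_grid=(0.01,), tc_max=1,
                  n_trees=100, n_folds=5, seed=7)
        r1 = tune_and_cross_validate(data, [("a", "b")], **kw)
        r2 = tune_and_cross_validate(data, [("a", "b")], **kw)
        np.testing.assert_allclose(r1[0].fold_tss, r2[0].fold_tss)
        np.testing.assert_allclose(r1[0].fold_deviance, r2[0].fold_deviance)

    def test_informative_beats_noise(self):
        data = toy_cv_data(n=200, seed=1)
        res = tune_and_cross_validate(
            data, [("a",), ("b",)], monotone={}, lr_grid=(0.01,), tc_max=1,
            n_trees=300, n_folds=5, seed=0)
        by = {r.combination: r for r in res}
        assert by[("a",)].mean_tss > by[("b",)].mean_tss

    def test_single_point_composition(self):
        from nichecarver.cv import _cv_one, _fold_seed, make_longitudinal_folds

        data = toy_cv_data(seed=2)
        res = tune_and_cross_validate(
            data, [("a", "b")], monotone={}, lr_grid=(0.01,), tc_max=1,
            n_trees=100, n_folds=5, seed=3)[0]
        folds = make_longitudinal_folds(data["lon"].to_numpy(), 5)
        params = BRTParams(learning_rate=0.01, n_trees=100, tree_complexity=1,
                           bag_fraction=0.5, monotone=(0, 0),
                           seed=_fold_seed(3, 0, 0))
        tss, dev, dev_exp = _cv_one(data[["a", "b"]].to_numpy(),
                                    data["y"].to_numpy(dtype=float), folds,
                                    params, [0, 0], ["a", "b"])
        np.testing.assert_allclose(res.fold_tss, tss)
        np.testing.assert_allclose(res.fold_deviance, dev)


def cv_result(combo, tss, deviance=None):
    tss = np.asarray(tss, dtype=float)
    dev = (np.full(tss.size, np.nan) if deviance is None
           else np.full(tss.size, float(deviance)))
    return CVResult(combination=tuple(combo), best_params=BRTParams(),
                    fold_tss=tss, fold_deviance=dev,
                    fold_dev_explained=np.full(tss.size, np.nan))


class TestSelectModels:
    def test_identical_vectors_all_retained(self):
        folds = [0.8] * 10
        res = [cv_result(c, folds) for c in (("a", "b"), ("a", "c"), ("b", "c"))]
        ms = select_models(res)
        assert len(ms.members) == 3

    def test_disjoint_fold_tss_rejected(self):
        good = cv_result(("a", "b"), np.linspace(0.85, 0.95, 10))
        bad = cv_result(("c", "d"), np.linspace(0.05, 0.15, 10))
        ms = select_models([good, bad])
        assert ms.combinations == [("a", "b")]
        # the disjoint two-group 10-fold case has H = 14.29 exactly
        H, _ = kruskal(good.fold_tss, bad.fold_tss)
        assert H == pytest.approx(14.2857, abs=1e-3)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        res = [cv_result((f"p{i}", "q"), rng.uniform(0.3, 0.9, 10))
               for i in range(6)]
        a = select_models(res)
        b = select_models(list(reversed(res)))
        assert a.combinations == b.combinations

    def test_kruskal_wallis_matches_rank_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=10)
            z = rng.normal(size=10)
            H_scipy, _ = kruskal(x, z)
            # independent computation from the rank-sum formula (no ties)
            ranks = pd.Series(np.concatenate([x, z])).rank().to_numpy()
            N = 20
            H = (12 / (N * (N + 1))
                 * (ranks[:10].sum() ** 2 / 10 + ranks[10:].sum() ** 2 / 10)
                 - 3 * (N + 1))
            assert H_scipy == pytest.approx(H, rel=1e-9)


class TestPredictorContribution:
    def test_exact_arithmetic_on_constructed_results(self):
        res = [
            cv_result(("a", "b"), [0.5] * 10, deviance=1.0),
            cv_result(("a", "b", "j"), [0.5] * 10, deviance=0.4),
            cv_result(("a", "c"), [0.5] * 10, deviance=0.9),
            cv_result(("a", "c", "j"), [0.5] * 10, deviance=0.7),
        ]
        df = predictor_contribution(res).set_index("predictor")
        # j: mean of (1.0-0.4) and (0.9-0.7) = 0.4
        assert df.loc["j", "mean_deviance_decrease"] == pytest.approx(0.4)
        assert df.loc["j", "n_pairs"] == 2
        assert df["contribution_pct"].sum() == pytest.approx(100.0)

    def test_predictor_without_pairs_flagged(self):
        res = [cv_result(("a", "b"), [0.5] * 10, deviance=1.0)]
        df = predictor_contribution(res).set_index("predictor")
        assert (df["flag"] == "no (C, C+j) pair").all()
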