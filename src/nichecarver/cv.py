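"""Spatial-band cross-validation, TSS evaluation and model-set selection.

Transferability is measured by withholding one of 10 longitudinal bands of
records at a time: candidate predictor combinations (pairwise |Pearson r|
below a collinearity cap) are tuned over a small hyperparameter grid, scored
by held-out Bernoulli deviance, and the combinations statistically
indistinguishable from the best (Kruskal-Wallis on fold-wise TSS) form the
ensemble member set.  Per-predictor contribution is the mean held-out
deviance decrease from adding the predictor to alternative combinations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .brt import BRTModel, BRTParams, bernoulli_deviance, fit_brt

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Predictor-combination enumeration


def correlation_filter(predictors, r_max: float = 0.8, min_size: int = 2,
                       max_size: int | None = None,
                       max_combinations: int = 500,
                       seed: int = 0) -> list[tuple[str, ...]]:
    """All predictor combinations with pairwise |Pearson r| < r_max.

    Correlations are computed over cells valid in both rasters.  Enumeration
    is over subset sizes min_size..max_size; when the admissible list
    exceeds ``max_combinations`` a seeded uniform sample of that size is
    returned.
    """
    names = [p.name for p in predictors]
    p = len(names)
    if p < 1:
        raise ValueError("need at least one predictor")
    flat = [pr.raster.values.ravel() for pr in predictors]
    compatible = np.ones((p, p), dtype=bool)
    for i, j in itertools.combinations(range(p), 2):
        ok = np.isfinite(flat[i]) & np.isfinite(flat[j])
        r = np.corrcoef(flat[i][ok], flat[j][ok])[0, 1] if ok.sum() > 2 else 1.0
        compatible[i, j] = compatible[j, i] = abs(r) < r_max
    if max_size is None:
        max_size = p
    combos: list[tuple[str, ...]] = []
    for size in range(min_size, max_size + 1):
        for sub in itertools.combinations(range(p), size):
            if all(compatible[a, b] for a, b in itertools.combinations(sub, 2)):
                combos.append(tuple(names[k] for k in sub))
    if not combos:
        raise ValueError("no admissible predictor combination under "
                         f"|r| < {r_max}")
    if len(combos) > max_combinations:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(combos), size=max_combinations, replace=False)
        combos = [combos[k] for k in sorted(keep)]
    return combos


# ---------------------------------------------------------------------------
# Folds


@dataclasses.dataclass
class FoldAssignment:
    """Record -> longitudinal band index (0-based), bands ordered west-east."""

    fold: np.ndarray          # per record
    boundaries: np.ndarray    # internal longitude cut points, length n_folds-1

    @property
    def n_folds(self) -> int:
        return int(self.fold.max()) + 1


def make_longitudinal_folds(lon, n_folds: int = 10) -> FoldAssignment:
    """Sort records by longitude and cut into n_folds equal-count (+-1)
    contiguous bands."""
    lon = np.asarray(lon, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if lon.size < n_folds:
        raise ValueError(f"need at least {n_folds} records")
    order = np.argsort(lon, kind="mergesort")
    fold = np.empty(lon.size, dtype=int)
    chunks = np.array_split(np.arange(lon.size), n_folds)
    bounds = []
    for k, chunk in enumerate(chunks):
        fold[order[chunk]] = k
        if k < n_folds - 1:
            lo = lon[order[chunk[-1]]]
            hi = lon[order[chunks[k + 1][0]]]
            bounds.append(0.5 * (lo + hi))
    return FoldAssignment(fold=fold, boundaries=np.asarray(bounds))


# ---------------------------------------------------------------------------
# TSS


@dataclasses.dataclass(frozen=True)
class ConfusionStats:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def tss_at_threshold(p_pred, y_obs, threshold: float) -> ConfusionStats:
    """Sensitivity/specificity of ``p_pred >= threshold`` against y_obs."""
    p_pred = np.asarray(p_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    n_pos = int((y_obs == 1).sum())
    n_neg = int((y_obs == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pred = p_pred >= threshold
    sens = float((pred & (y_obs == 1)).sum() / n_pos)
    spec = float((~pred & (y_obs == 0)).sum() / n_neg)
    return ConfusionStats(threshold=float(threshold), sensitivity=sens,
                          specificity=spec)


def evaluate_tss(p_pred, y_obs) -> ConfusionStats:
    """Threshold maximizing sensitivity + specificity.

    Scans every distinct predicted value and the midpoints between
    consecutive values (prediction >= threshold -> presence); among ties the
    lowest maximizing threshold is kept, favouring sensitivity.
    """
    p_pred = np.asarray(p_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    n_pos = int((y_obs == 1).sum())
    n_neg = int((y_obs == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(p_pred)
    cand = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]])
    cand = np.unique(cand)
    pos_sorted = np.sort(p_pred[y_obs == 1])
    neg_sorted = np.sort(p_pred[y_obs == 0])
    # predicted presence: p >= t
    sens = 1.0 - np.searchsorted(pos_sorted, cand, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, cand, side="left") / n_neg
    tss = sens + spec
    best = int(np.argmax(tss))  # argmax returns the first (lowest) maximizer
    return ConfusionStats(threshold=float(cand[best]),
                          sensitivity=float(sens[best]),
                          specificity=float(spec[best]))


# ---------------------------------------------------------------------------
# Tuning and cross-validation


@dataclasses.dataclass
class CVResult:
    """Fold-wise performance of one predictor combination at its best
    hyperparameters (NaN folds were skipped for lacking both classes)."""

    combination: tuple[str, ...]
    best_params: BRTParams
    fold_tss: np.ndarray
    fold_deviance: np.ndarray
    fold_dev_explained: np.ndarray

    @property
    def mean_tss(self) -> float:
        return float(np.nanmean(self.fold_tss))

    @property
    def mean_deviance(self) -> float:
        return float(np.nanmean(self.fold_deviance))

    @property
    def mean_dev_explained(self) -> float:
        return float(np.nanmean(self.fold_dev_explained))


def _fold_seed(master: int, *idx: int) -> int:
    ss = np.random.SeedSequence([int(master) % (2 ** 31), *[i % (2 ** 31) for i in idx]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _cv_one(X, y, folds: FoldAssignment, params: BRTParams, monotone,
            feature_names) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_folds = folds.n_folds
    tss = np.full(n_folds, np.nan)
    dev = np.full(n_folds, np.nan)
    dev_exp = np.full(n_folds, np.nan)
    for k in range(n_folds):
        test = folds.fold == k
        train = ~test
        y_tr, y_te = y[train], y[test]
        if len(set(y_te)) < 2 or len(set(y_tr)) < 2:
            logger.warning("fold %d skipped: single-class data", k)
            continue
        prm = dataclasses.replace(params, monotone=tuple(monotone),
                                  seed=_fold_seed(params.seed, k))
        model = fit_brt(X[train], y_tr, prm, feature_names)
        p_te = model.predict(X[test])
        dev[k] = bernoulli_deviance(y_te, p_te)
        null = bernoulli_deviance(y_te, np.full(y_te.size, y_tr.mean()))
        dev_exp[k] = 1.0 - dev[k] / null if null > 0 else np.nan
        # the maximizing threshold comes from the training rows and is
        # applied to the withheld band: optimizing it on the test band
        # would inflate TSS for skill-free models
        thr = evaluate_tss(model.predict(X[train]), y_tr).threshold
        tss[k] = tss_at_threshold(p_te, y_te, thr).tss
    return tss, dev, dev_exp


def tune_and_cross_validate(data: pd.DataFrame, combinations,
                            monotone: dict[str, int],
                            lr_grid=(0.01, 0.005, 0.001, 0.0005),
                            tc_max: int | None = None,
                            n_trees: int = 2000, bag_fraction: float = 0.5,
                            n_folds: int = 10, seed: int = 0) -> list[CVResult]:
    """Hyperparameter tuning and longitudinal-band CV per combination.

    `data` carries one row per record with predictor columns plus ``y``
    (0/1) and ``lon``.  For each combination the (lr, tc) grid point with
    the lowest mean held-out deviance wins (tc runs from 1 to the number of
    predictors in the combination, capped by ``tc_max``); at least
    ``n_trees`` trees are grown at every grid point.
    """
    if not combinations:
        raise ValueError("no combinations to evaluate")
    y = data["y"].to_numpy(dtype=float)
    folds = make_longitudinal_folds(data["lon"].to_numpy(), n_folds)
    results: list[CVResult] = []
    for ci, combo in enumerate(combinations):
        X = data.loc[:, list(combo)].to_numpy(dtype=float)
        signs = [monotone.get(name, 0) for name in combo]
        tcs = range(1, len(combo) + 1 if tc_max is None
                    else min(tc_max, len(combo)) + 1)
        best = None
        for hi, (lr, tc) in enumerate(itertools.product(lr_grid, tcs)):
            params = BRTParams(learning_rate=lr, n_trees=n_trees,
                               tree_complexity=tc, bag_fraction=bag_fraction,
                               monotone=tuple(signs),
                               seed=_fold_seed(seed, ci, hi))
            tss, dev, dev_exp = _cv_one(X, y, folds, params, signs, list(combo))
            mean_dev = float(np.nanmean(dev))
            if best is None or mean_dev < best[0]:
                best = (mean_dev, params, tss, dev, dev_exp)
        _, params, tss, dev, dev_exp = best
        results.append(CVResult(combination=tuple(combo), best_params=params,
                                fold_tss=tss, fold_deviance=dev,
                                fold_dev_explained=dev_exp))
    return results


# ---------------------------------------------------------------------------
# Model-set selection and predictor contribution


@dataclasses.dataclass
class ModelSet:
    """Combinations retained as statistically equivalent in transferability."""

    members: list[CVResult]
    rejected: list[CVResult]

    @property
    def combinations(self) -> list[tuple[str, ...]]:
        return [m.combination for m in self.members]


def select_models(cv_results: list[CVResult], alpha: float = 0.05) -> ModelSet:
    """Greedy descent from the highest mean TSS.

    Candidates are taken in decreasing mean-TSS order; each is compared to
    the *best* combination's fold-TSS vector with a two-group Kruskal-Wallis
    rank test and retained while the null of equal performance is not
    rejected at `alpha`.  Selection stops at the first rejection.  All-equal
    (zero-variance) TSS vectors are retained.

    Two anchoring choices keep the descent from admitting ever-weaker
    models: the reference is the fixed best vector (a pooled reference
    drifts downward as mediocre combinations accumulate), and the test is
    one-sided — the descent asks whether the candidate is *inferior* to the
    best, and by construction its mean never exceeds the reference's, so
    the two-sided p is halved.
    """
    if len(cv_results) < 2:
        return ModelSet(members=list(cv_results), rejected=[])
    order = sorted(range(len(cv_results)),
                   key=lambda i: (-cv_results[i].mean_tss,
                                  cv_results[i].combination))
    best = cv_results[order[0]]
    ref = best.fold_tss[np.isfinite(best.fold_tss)]
    members = [best]
    rejected: list[CVResult] = []
    stopped = False
    for i in order[1:]:
        cand = cv_results[i]
        if stopped:
            rejected.append(cand)
            continue
        own = cand.fold_tss[np.isfinite(cand.fold_tss)]
        try:
            _, p = kruskal(ref, own)
            p = p / 2.0          # one-sided: candidate worse than best
        except ValueError:       # all values identical -> indistinguishable
            p = 1.0
        if p < alpha:
            stopped = True
            rejected.append(cand)
        else:
            members.append(cand)
    return ModelSet(members=members, rejected=rejected)


def discard_null_contributors(cv_results: list[CVResult],
                              contributions: pd.DataFrame) -> list[CVResult]:
    """Drop combinations containing predictors with null contribution.

    Predictors whose mean held-out deviance decrease is not positive add
    nothing but noise to the ensemble; combinations using them are removed
    from the candidate set before model-set selection (an overfitting
    guard).  Predictors with no computable contribution are kept.  If
    pruning would empty the candidate list it is skipped.
    """
    null = set(contributions.loc[
        contributions["mean_deviance_decrease"] <= 0, "predictor"])
    if not null:
        return list(cv_results)
    kept = [r for r in cv_results if not (set(r.combination) & null)]
    if not kept:
        logger.warning("null-contribution pruning would drop every "
                       "combination; keeping all")
        return list(cv_results)
    logger.info("discarded %d combinations using null-contribution "
                "predictors %s", len(cv_results) - len(kept), sorted(null))
    return kept


def predictor_contribution(cv_results: list[CVResult]) -> pd.DataFrame:
    """Mean held-out deviance decrease from adding each predictor.

    For every pair of evaluated combinations (C, C ∪ {j}) the decrease
    deviance(C) - deviance(C ∪ {j}) is averaged per predictor; percentages
    are of the sum of positive contributions.  Predictors with no valid
    pair are flagged.
    """
    by_combo = {frozenset(r.combination): r.mean_deviance for r in cv_results}
    predictors = sorted({name for r in cv_results for name in r.combination})
    rows = []
    for name in predictors:
        deltas = []
        for combo, dev_with in by_combo.items():
            if name not in combo:
                continue
            base = combo - {name}
            if base in by_combo:
                deltas.append(by_combo[base] - dev_with)
        rows.append({"predictor": name,
                     "mean_deviance_decrease": (float(np.mean(deltas))
                                                if deltas else np.nan),
                     "n_pairs": len(deltas),
                     "flag": "" if deltas else "no (C, C+j) pair"})
    df = pd.DataFrame(rows)
    pos = df["mean_deviance_decrease"].clip(lower=0.0)
    total = pos.sum(skipna=True)
    df["contribution_pct"] = 100.0 * pos / total if total > 0 else np.nan
    return df.sort_values("contribution_pct", ascending=False,
                          na_position="last").reset_index(drop=True)
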