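"""Stochastic gradient-boosted regression trees for binary responses.

A from-scratch boosting core tailored to niche modelling: Bernoulli deviance
loss, shrinkage, bag fraction, tree-complexity control (number of splits per
tree) and per-predictor monotone constraints.  Stage m draws a bag of rows
without replacement, fits a small regression tree to the negative gradient
(y - p) by greedy best-first splitting on squared-error reduction, sets leaf
values by a single Newton step, and adds the tree with shrinkage.

Monotone constraints are enforced at split time: a split on a constrained
predictor is rejected when its child values violate the required order, and
the midpoint of the accepted child values bounds every descendant leaf, so
each tree — hence the whole additive model — is monotone in the constrained
predictor.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from numba import njit

_EPS = 1e-9


def bernoulli_deviance(y, p) -> float:
    """Mean Bernoulli deviance, -2 mean(y log p + (1-y) log(1-p)).

    Probabilities are clipped to [1e-9, 1 - 1e-9].
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise ValueError("empty vectors")
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclasses.dataclass(frozen=True)
class BRTParams:
    """Boosting hyperparameters.

    learning_rate: shrinkage applied to every tree's contribution.
    n_trees: number of boosting stages.
    tree_complexity: splits per tree (1 = stumps).
    bag_fraction: fraction of rows drawn (without replacement) per stage.
    monotone: per-predictor constraint signs (+1 non-decreasing,
      -1 non-increasing, 0 free), aligned with the columns of X.
    """

    learning_rate: float = 0.01
    n_trees: int = 2000
    tree_complexity: int = 1
    bag_fraction: float = 0.5
    monotone: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _fit_core(X, y, lr, nt, tc, bag, monotone, seed):  # pragma: no cover
    n, p = X.shape
    max_nodes = 2 * tc + 1
    t_feat = np.full((nt, max_nodes), -1, dtype=np.int64)
    t_thr = np.zeros((nt, max_nodes))
    t_val = np.zeros((nt, max_nodes))
    t_left = np.full((nt, max_nodes), -1, dtype=np.int64)
    t_right = np.full((nt, max_nodes), -1, dtype=np.int64)

    prev = y.mean()
    intercept = np.log(prev / (1.0 - prev))
    F = np.full(n, intercept)
    trace = np.zeros(nt)

    m_bag = max(1, int(round(bag * n)))
    np.random.seed(seed)
    perm_buf = np.arange(n)

    node_of = np.empty(n, dtype=np.int64)
    # per-node bookkeeping within one tree
    n_lo = np.empty(max_nodes)
    n_hi = np.empty(max_nodes)
    best_gain = np.empty(max_nodes)
    best_feat = np.empty(max_nodes, dtype=np.int64)
    best_thr = np.empty(max_nodes)
    best_vl = np.empty(max_nodes)
    best_vr = np.empty(max_nodes)
    is_leaf = np.empty(max_nodes, dtype=np.bool_)

    for m in range(nt):
        prob = _sigmoid(F)
        res = y - prob
        hess = prob * (1.0 - prob)

        # bag: partial Fisher-Yates without replacement
        if m_bag < n:
            for i in range(m_bag):
                j = i + np.random.randint(0, n - i)
                tmp = perm_buf[i]
                perm_buf[i] = perm_buf[j]
                perm_buf[j] = tmp
            rows = perm_buf[:m_bag].copy()
        else:
            rows = perm_buf

        # grow one tree, best-first
        n_nodes = 1
        for i in rows:
            node_of[i] = 0
        n_lo[0] = -1e300
        n_hi[0] = 1e300
        is_leaf[0] = True
        _eval_node(X, res, hess, rows, node_of, 0, monotone,
                   n_lo, n_hi, best_gain, best_feat, best_thr, best_vl, best_vr)

        for _ in range(tc):
            # pick the leaf with the best admissible split
            node = -1
            g = 0.0
            for q in range(n_nodes):
                if is_leaf[q] and best_gain[q] > g:
                    g = best_gain[q]
                    node = q
            if node < 0:
                break
            f = best_feat[node]
            thr = best_thr[node]
            lc = n_nodes
            rc = n_nodes + 1
            n_nodes += 2
            t_feat[m, node] = f
            t_thr[m, node] = thr
            t_left[m, node] = lc
            t_right[m, node] = rc
            is_leaf[node] = False
            is_leaf[lc] = True
            is_leaf[rc] = True
            s = monotone[f]
            vl = best_vl[node]
            vr = best_vr[node]
            if s == 0:
                n_lo[lc] = n_lo[node]; n_hi[lc] = n_hi[node]
                n_lo[rc] = n_lo[node]; n_hi[rc] = n_hi[node]
            else:
                mid = 0.5 * (vl + vr)
                if s > 0:
                    n_lo[lc] = n_lo[node]; n_hi[lc] = mid
                    n_lo[rc] = mid; n_hi[rc] = n_hi[node]
                else:
                    n_lo[lc] = mid; n_hi[lc] = n_hi[node]
                    n_lo[rc] = n_lo[node]; n_hi[rc] = mid
            for i in rows:
                if node_of[i] == node:
                    node_of[i] = lc if X[i, f] <= thr else rc
            _eval_node(X, res, hess, rows, node_of, lc, monotone, n_lo, n_hi,
                       best_gain, best_feat, best_thr, best_vl, best_vr)
            _eval_node(X, res, hess, rows, node_of, rc, monotone, n_lo, n_hi,
                       best_gain, best_feat, best_thr, best_vl, best_vr)

        # set leaf values (one Newton step, clipped to monotone bounds)
        for q in range(n_nodes):
            if not is_leaf[q]:
                continue
            sr = 0.0
            sh = 0.0
            for i in rows:
                if node_of[i] == q:
                    sr += res[i]
                    sh += hess[i]
            v = sr / sh if sh > 1e-12 else 0.0
            if v < n_lo[q]:
                v = n_lo[q]
            if v > n_hi[q]:
                v = n_hi[q]
            t_val[m, q] = v

        # update F on ALL rows
        for i in range(n):
            q = 0
            while t_feat[m, q] >= 0:
                q = t_left[m, q] if X[i, t_feat[m, q]] <= t_thr[m, q] \
                    else t_right[m, q]
            F[i] += lr * t_val[m, q]

        prob = _sigmoid(F)
        dev = 0.0
        for i in range(n):
            pi = min(max(prob[i], 1e-9), 1 - 1e-9)
            dev += y[i] * np.log(pi) + (1.0 - y[i]) * np.log(1.0 - pi)
        trace[m] = -2.0 * dev / n

    return intercept, t_feat, t_thr, t_val, t_left, t_right, trace


@njit(cache=True)
def _eval_node(X, res, hess, rows, node_of, node, monotone, n_lo, n_hi,
               best_gain, best_feat, best_thr, best_vl, best_vr):  # pragma: no cover
    """Best admissible split of `node`, written into the best_* arrays."""
    m = 0
    for i in rows:
        if node_of[i] == node:
            m += 1
    best_gain[node] = 0.0
    best_feat[node] = -1
    if m < 2:
        return
    idx = np.empty(m, dtype=np.int64)
    k = 0
    for i in rows:
        if node_of[i] == node:
            idx[k] = i
            k += 1
    p = X.shape[1]
    lo = n_lo[node]
    hi = n_hi[node]
    g_best = 0.0
    for f in range(p):
        vals = np.empty(m)
        for k in range(m):
            vals[k] = X[idx[k], f]
        order = np.argsort(vals, kind="mergesort")
        s_tot = 0.0
        h_tot = 0.0
        for k in range(m):
            s_tot += res[idx[k]]
            h_tot += hess[idx[k]]
        s_left = 0.0
        h_left = 0.0
        n_left = 0.0
        base = s_tot * s_tot / m
        sgn = monotone[f]
        for k in range(m - 1):
            i = idx[order[k]]
            s_left += res[i]
            h_left += hess[i]
            n_left += 1.0
            v_here = vals[order[k]]
            v_next = vals[order[k + 1]]
            if v_here == v_next:
                continue
            n_right = m - n_left
            gain = (s_left * s_left / n_left
                    + (s_tot - s_left) * (s_tot - s_left) / n_right - base)
            if gain <= g_best:
                continue
            vl = s_left / h_left if h_left > 1e-12 else 0.0
            vr = ((s_tot - s_left) / (h_tot - h_left)
                  if (h_tot - h_left) > 1e-12 else 0.0)
            if vl < lo:
                vl = lo
            if vl > hi:
                vl = hi
            if vr < lo:
                vr = lo
            if vr > hi:
                vr = hi
            if sgn > 0 and vr < vl:
                continue
            if sgn < 0 and vr > vl:
                continue
            g_best = gain
            best_gain[node] = gain
            best_feat[node] = f
            best_thr[node] = 0.5 * (v_here + v_next)
            best_vl[node] = vl
            best_vr[node] = vr


@njit(cache=True)
def _predict_raw(X, t_feat, t_thr, t_val, t_left, t_right, intercept,
                 lr, nt):  # pragma: no cover
    n = X.shape[0]
    out = np.full(n, intercept)
    for i in range(n):
        acc = 0.0
        for m in range(nt):
            q = 0
            while t_feat[m, q] >= 0:
                q = t_left[m, q] if X[i, t_feat[m, q]] <= t_thr[m, q] \
                    else t_right[m, q]
            acc += t_val[m, q]
        out[i] += lr * acc
    return out


@dataclasses.dataclass
class BRTModel:
    """A fitted boosted-tree model.

    Prediction is logistic(intercept + lr * sum of tree outputs); the
    intercept is the log-odds of the training prevalence.
    """

    intercept: float
    params: BRTParams
    feature_names: list[str]
    t_feat: np.ndarray
    t_thr: np.ndarray
    t_val: np.ndarray
    t_left: np.ndarray
    t_right: np.ndarray
    train_deviance: np.ndarray

    @property
    def n_trees(self) -> int:
        return self.t_feat.shape[0]

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X must have {len(self.feature_names)} columns "
                f"({self.feature_names})")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        return X

    def predict_raw(self, X) -> np.ndarray:
        X = self._check_X(X)
        return _predict_raw(X, self.t_feat, self.t_thr, self.t_val,
                            self.t_left, self.t_right, self.intercept,
                            self.params.learning_rate, self.n_trees)

    def predict(self, X) -> np.ndarray:
        """Occurrence probabilities in (0, 1)."""
        return 1.0 / (1.0 + np.exp(-self.predict_raw(X)))

    def partial_dependence(self, X, feature: str | int, grid) -> np.ndarray:
        """Mean prediction over rows of X with `feature` forced to each
        grid value (probability scale)."""
        X = self._check_X(X)
        j = (feature if isinstance(feature, int)
             else _feature_index(self.feature_names, feature))
        grid = np.asarray(grid, dtype=float)
        out = np.empty(grid.size)
        Xmod = X.copy()
        for k, v in enumerate(grid):
            Xmod[:, j] = v
            out[k] = float(np.mean(self.predict(Xmod)))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept,
            "params": dataclasses.asdict(self.params),
            "feature_names": self.feature_names,
            "trees": {
                "feat": self.t_feat.tolist(),
                "thr": self.t_thr.tolist(),
                "val": self.t_val.tolist(),
                "left": self.t_left.tolist(),
                "right": self.t_right.tolist(),
            },
            "train_deviance": self.train_deviance.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "BRTModel":
        d = json.loads(text)
        prm = dict(d["params"])
        prm["monotone"] = tuple(prm["monotone"])
        return cls(
            intercept=d["intercept"],
            params=BRTParams(**prm),
            feature_names=list(d["feature_names"]),
            t_feat=np.asarray(d["trees"]["feat"], dtype=np.int64),
            t_thr=np.asarray(d["trees"]["thr"], dtype=float),
            t_val=np.asarray(d["trees"]["val"], dtype=float),
            t_left=np.asarray(d["trees"]["left"], dtype=np.int64),
            t_right=np.asarray(d["trees"]["right"], dtype=np.int64),
            train_deviance=np.asarray(d["train_deviance"], dtype=float),
        )


def _feature_index(names: list[str], feature: str) -> int:
    try:
        return names.index(feature)
    except ValueError:
        raise KeyError(f"unknown predictor {feature!r}") from None


def fit_brt(X, y, params: BRTParams, feature_names=None) -> BRTModel:
    """Fit a monotone-constrained boosted-tree model.

    X must be complete (no missing values); y binary with both classes
    present.  Fully deterministic given params.seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; mask cells upstream")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must contain both classes (0 and 1)")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")
    monotone = np.asarray(params.monotone if params.monotone
                          else np.zeros(p), dtype=np.int64)
    if monotone.size != p:
        raise ValueError("monotone must have one sign per predictor")
    intercept, t_feat, t_thr, t_val, t_left, t_right, trace = _fit_core(
        X, y, float(params.learning_rate), int(params.n_trees),
        int(params.tree_complexity), float(params.bag_fraction),
        monotone, int(params.seed) % (2 ** 32 - 1),
    )
    return BRTModel(intercept=float(intercept), params=params,
                    feature_names=list(feature_names),
                    t_feat=t_feat, t_thr=t_thr, t_val=t_val,
                    t_left=t_left, t_right=t_right, train_deviance=trace)


def predict_brt(model: BRTModel, X) -> np.ndarray:
    """Functional alias for model.predict."""
    return model.predict(X)


def partial_dependence(model: BRTModel, X, feature, grid) -> np.ndarray:
    """Functional alias for model.partial_dependence."""
    return model.partial_dependence(X, feature, grid)
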