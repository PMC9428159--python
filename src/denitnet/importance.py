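"""Permutation-based predictor importance with a response-permutation null.

A bagged regression-tree ensemble is fit to the response (PDA or cumulative
N2O); predictor importance is the out-of-bag (OOB) permutation increase in
mean-squared error, floored at zero and normalized to percentages that sum
to 100. Significance per predictor comes from a response-permutation null:
the ensemble is refit on permuted responses and

    p_perm = (1 + #{null importance >= observed}) / (n_response_perms + 1).

The bagging/OOB bookkeeping lives here so the importance definition is
explicit; the base learner is a standard regression tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeRegressor


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, max_features,
                min_samples_leaf: int, rng: np.random.Generator):
    """Bagged trees with explicit bootstrap bookkeeping.

    Returns list of (tree, oob_index_array); trees whose bootstrap happens
    to cover every sample are kept but contribute nothing to OOB scores.
    """
    n = len(y)
    forest = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(max_features=max_features,
                                     min_samples_leaf=min_samples_leaf,
                                     random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[boot], y[boot])
        forest.append((tree, oob))
    return forest


def _raw_importance(forest, X: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Mean over trees of (OOB MSE after permuting column j) - (OOB MSE)."""
    p = X.shape[1]
    total = np.zeros(p)
    used = 0
    for tree, oob in forest:
        if oob.size == 0:
            continue
        used += 1
        Xo, yo = X[oob], y[oob]
        base = np.mean((yo - tree.predict(Xo)) ** 2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            total[j] += np.mean((yo - tree.predict(Xp)) ** 2) - base
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return total / used


class RandomForestPermutationImportance(BaseEstimator):
    """Rank predictors of a per-sample response by OOB permutation importance.

    Parameters
    ----------
    n_trees : ensemble size (500, the common random-forest default).
    max_features : features tried per split; 1/3 mirrors the regression
        default of classic random forests.
    min_samples_leaf : minimum leaf size (5, the regression default).
    n_response_perms : response permutations for the significance null (100).
    seed : RNG seed; the fit is deterministic given it.

    Attributes (after fit)
    ----------------------
    feature_names_ : predictor names.
    raw_importances_ : mean OOB increase in MSE per predictor.
    importances_ : floored-at-zero importances normalized to sum to 100 (%).
    pvalues_ : response-permutation p per predictor.
    oob_mse_ : ensemble OOB mean-squared error.
    report_ : tidy frame (predictor, importance_pct, p_perm, significance).
    """

    def __init__(self, n_trees: int = 500, max_features=1.0 / 3,
                 min_samples_leaf: int = 5, n_response_perms: int = 100,
                 seed: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_response_perms = n_response_perms
        self.seed = seed

    def _raw_for(self, X, y, rng):
        forest = _fit_forest(X, y, self.n_trees, self.max_features,
                             self.min_samples_leaf, rng)
        return forest, _raw_importance(forest, X, y, rng)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 10:
            raise ValueError("need at least 10 samples")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("missing or non-finite values are not supported")
        if np.std(y) == 0:
            raise ValueError("constant response; importance undefined")
        rng = np.random.default_rng(self.seed)
        forest, raw = self._raw_for(X, y, rng)
        floored = np.clip(raw, 0.0, None)
        if floored.sum() == 0:
            pct = np.full(X.shape[1], 100.0 / X.shape[1])
        else:
            pct = 100.0 * floored / floored.sum()
        exceed = np.zeros(X.shape[1])
        for _ in range(self.n_response_perms):
            y_perm = rng.permutation(y)
            _, null_raw = self._raw_for(X, y_perm, rng)
            exceed += null_raw >= raw
        pvals = (1.0 + exceed) / (self.n_response_perms + 1.0)
        # ensemble OOB prediction for reference
        n = len(y)
        pred_sum, pred_cnt = np.zeros(n), np.zeros(n)
        for tree, oob in forest:
            if oob.size:
                pred_sum[oob] += tree.predict(X[oob])
                pred_cnt[oob] += 1
        covered = pred_cnt > 0
        self.oob_mse_ = float(np.mean(
            (y[covered] - pred_sum[covered] / pred_cnt[covered]) ** 2))
        self.feature_names_ = names
        self.raw_importances_ = raw
        self.importances_ = pct
        self.pvalues_ = pvals
        self.report_ = pd.DataFrame({
            "predictor": names,
            "importance_pct": pct,
            "p_perm": pvals,
            "significant_05": pvals < 0.05,
            "significant_01": pvals < 0.01,
        }).sort_values("importance_pct", ascending=False).reset_index(drop=True)
        return self


def importance(predictors: pd.DataFrame, response, n_trees: int = 500,
               n_response_perms: int = 100, seed: int = 0) -> pd.DataFrame:
    """Functional wrapper: fit the estimator and return its report frame."""
    est = RandomForestPermutationImportance(
        n_trees=n_trees, n_response_perms=n_response_perms, seed=seed)
    est.fit(predictors, response)
    return est.report_
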