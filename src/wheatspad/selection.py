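"""Cross-validated recursive feature elimination with a random forest.

Features are ranked by eliminating one variable per step, always dropping
the one with the lowest random-forest impurity importance.  The learning
curve then scores every retained size n = 1..p by mean 5-fold
cross-validated R^2 of the forest restricted to the top-n features.  The
"appropriate" size is the curve argmax (ties toward the smallest n); a
one-standard-error rule is available for flatter curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.model_selection import KFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


def choose_optimal_n(curve: pd.DataFrame, rule: str = "argmax",
                     folds: int = 5) -> int:
    """Pick the retained-feature count from a learning curve.

    ``curve`` needs columns ``n_features``/``mean_score``/``sd_score``.
    ``argmax``: highest mean score, ties toward the smallest n.
    ``one_se``: smallest n within one standard error of the best mean.
    """
    if len(curve) == 0:
        raise ValueError("empty learning curve")
    mean = curve["mean_score"].to_numpy()
    ns = curve["n_features"].to_numpy()
    order = np.argsort(ns)
    mean, ns = mean[order], ns[order]
    best = mean.max()
    if rule == "argmax":
        return int(ns[mean == best][0])
    if rule == "one_se":
        sd = curve["sd_score"].to_numpy()[order]
        i_best = int(np.nonzero(mean == best)[0][0])
        threshold = best - sd[i_best] / np.sqrt(folds)
        return int(ns[mean >= threshold][0])
    raise ValueError("rule must be 'argmax' or 'one_se'")


class RFESelector(BaseEstimator, TransformerMixin):
    """Recursive feature elimination with a CV learning curve.

    Parameters
    ----------
    n_trees : forest size for both the importance ranking and the curve.
    folds : K for the cross-validated R^2 curve.
    seed : controls the forest and the CV shuffling.
    rule : 'argmax' (default) or 'one_se' size selection.
    standardize : z-score features inside each fit (train-fold statistics);
        the forest is scale-invariant, but this keeps a single
        preprocessing path with the downstream regressors.

    Fitted attributes
    -----------------
    ranking_ : elimination order per feature (1 = eliminated last).
    learning_curve_ : DataFrame (n_features, mean_score, sd_score).
    optimal_n_ : selected size.
    selected_features_ : names of the optimal subset.
    support_ : boolean mask over input columns.
    """

    def __init__(self, n_trees: int = 100, folds: int = 5, seed: int = 0,
                 rule: str = "argmax", standardize: bool = True):
        self.n_trees = n_trees
        self.folds = folds
        self.seed = seed
        self.rule = rule
        self.standardize = standardize

    def _estimator(self) -> Pipeline:
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("rf", RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed)))
        return Pipeline(steps)

    def fit(self, X, y):
        X_arr, names = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        n, p = X_arr.shape
        if p < 2:
            raise ValueError("need at least 2 candidate features")
        if n < self.folds:
            raise ValueError("fewer rows than CV folds")
        if np.ptp(y) == 0:
            raise ValueError("constant target")
        if not np.isfinite(X_arr).all():
            raise ValueError("non-finite feature values")

        est = self._estimator()
        rfe = RFE(clone(est), n_features_to_select=1, step=1,
                  importance_getter="named_steps.rf.feature_importances_")
        rfe.fit(X_arr, y)
        self.ranking_ = rfe.ranking_.copy()

        cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        records = []
        for size in range(1, p + 1):
            cols = self.ranking_ <= size
            scores = cross_val_score(clone(est), X_arr[:, cols], y,
                                     cv=cv, scoring="r2")
            records.append((size, scores.mean(), scores.std(ddof=0)))
        self.learning_curve_ = pd.DataFrame(
            records, columns=["n_features", "mean_score", "sd_score"])

        self.optimal_n_ = choose_optimal_n(self.learning_curve_,
                                           rule=self.rule, folds=self.folds)
        self.support_ = self.ranking_ <= self.optimal_n_
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.selected_features_ = [names[i] for i in range(p)
                                   if self.support_[i]]
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X_arr, names = _as_matrix(X)
        if X_arr.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_features_]
        return X_arr[:, self.support_]

    def plot_learning_curve(self, path=None, ax=None):
        """Learning-curve plot (mean +/- SD of CV R^2 vs retained size)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        c = self.learning_curve_
        ax.errorbar(c["n_features"], c["mean_score"], yerr=c["sd_score"],
                    fmt="-o", ms=3, lw=1, capsize=2)
        ax.axvline(self.optimal_n_, ls="--", color="gray", lw=1)
        ax.set_xlabel("number of retained variables")
        ax.set_ylabel("CV $R^2$")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names")
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    return X, [f"x{i}" for i in range(X.shape[1])]


def rfe_cv(X, y, n_trees: int = 100, folds: int = 5, seed: int = 0,
           rule: str = "argmax") -> RFESelector:
    """Functional wrapper: fit an :class:`RFESelector` and return it."""
    return RFESelector(n_trees=n_trees, folds=folds, seed=seed,
                       rule=rule).fit(X, y)
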