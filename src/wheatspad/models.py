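"""The four SPAD regressors with grid-searched hyperparameters.

Families: ridge regression, random forest, RBF support-vector regression,
and a single-hidden-layer back-propagation network (MLP).  Each family is
fitted by exhaustive grid search scored by mean K-fold CV R^2 on the
training set, then refitted on the full training set with the winning
combination.  Ridge/SVR/MLP consume z-scored features (scaler fitted on
training folds only, inside the CV pipeline); the forest consumes raw
features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

MODEL_FAMILIES = ("ridge", "rf", "svr", "bpnn")

#: grid-search spaces (the model parameter names are pipeline-prefixed)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {"model__alpha": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]},
    "rf": {"model__n_estimators": [100, 300, 500],
           "model__max_depth": [None, 5, 10]},
    # gamma entries are factors on the 'scale' heuristic, resolved at fit
    "svr": {"model__C": [0.1, 1.0, 10.0, 100.0],
            "model__gamma": ["scale:0.1", "scale:1", "scale:10"],
            "model__epsilon": [0.01, 0.1, 0.5]},
    "bpnn": {"model__hidden_layer_sizes": [(8,), (16,), (32,)],
             "model__activation": ["logistic", "relu"]},
}


def split_dataset(n_plots: int, train_fraction: float = 0.8,
                  seed: int = 0, folds: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random 8:2 split into (train, test) index arrays.

    Test size is round-half-up of (1 - train_fraction) * n, so ties go to
    the larger test set.  Indices are returned sorted.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n_plots < folds + 1:
        raise ValueError("too few plots to split and cross-validate")
    n_test = int(np.floor((1.0 - train_fraction) * n_plots + 0.5))
    n_test = max(1, min(n_test, n_plots - 1))
    perm = np.random.default_rng(seed).permutation(n_plots)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


class SpadRegressor(BaseEstimator, RegressorMixin):
    """Grid-searched SPAD regressor of one model family.

    Fitted attributes: ``best_params_`` (members of the supplied grid),
    ``cv_score_`` (mean CV R^2 of the winner), ``model_`` (refitted
    pipeline), ``feature_names_in_``.
    """

    def __init__(self, family: str = "ridge", grid: dict | None = None,
                 folds: int = 5, seed: int = 0):
        self.family = family
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def _pipeline(self) -> Pipeline:
        if self.family == "ridge":
            model = Ridge()
        elif self.family == "rf":
            model = RandomForestRegressor(random_state=self.seed)
        elif self.family == "svr":
            model = SVR(kernel="rbf")
        elif self.family == "bpnn":
            model = MLPRegressor(max_iter=2000, random_state=self.seed)
        else:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "rf":
            return Pipeline([("model", model)])
        return Pipeline([("scale", StandardScaler()), ("model", model)])

    def _resolved_grid(self, n_features: int) -> dict:
        source = self.grid if self.grid is not None \
            else DEFAULT_GRIDS[self.family]
        if not source:
            raise ValueError("empty hyperparameter grid")
        grid = {k: list(v) for k, v in source.items()}
        # resolve gamma 'scale' factors: after z-scoring, X.var() ~ 1, so
        # the scale heuristic is 1/n_features
        if "model__gamma" in grid:
            resolved = []
            for g in grid["model__gamma"]:
                if isinstance(g, str) and g.startswith("scale:"):
                    resolved.append(float(g.split(":")[1]) / n_features)
                else:
                    resolved.append(g)
            grid["model__gamma"] = resolved
        return grid

    def fit(self, X, y):
        X_arr, names = _check_X(X)
        y = np.asarray(y, dtype=float)
        if not (np.isfinite(X_arr).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in features or target")
        if len(y) < self.folds:
            raise ValueError("fewer training rows than CV folds")
        if self.family in ("ridge", "svr") and np.ptp(y) == 0:
            raise ValueError("degenerate (constant) target")
        pipe = self._pipeline()
        grid = self._resolved_grid(X_arr.shape[1])
        cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        gs = GridSearchCV(pipe, grid, scoring="r2", cv=cv,
                          refit=True, error_score="raise")
        gs.fit(X_arr, y)
        self.model_ = gs.best_estimator_
        self.best_params_ = gs.best_params_
        self.cv_score_ = float(gs.best_score_)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X_arr.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X_arr, names = _check_X(X)
        if isinstance(X, pd.DataFrame):
            if list(names) != list(self.feature_names_in_):
                raise ValueError("feature columns do not match training")
        elif X_arr.shape[1] != self.n_features_in_:
            raise ValueError("feature count does not match training")
        return self.model_.predict(X_arr)


def _check_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X, [f"x{i}" for i in range(X.shape[1])]


def train_model(X, y, family: str = "ridge", grid: dict | None = None,
                folds: int = 5, seed: int = 0) -> SpadRegressor:
    """Functional wrapper: fit a :class:`SpadRegressor` and return it."""
    return SpadRegressor(family=family, grid=grid, folds=folds,
                         seed=seed).fit(X, y)
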