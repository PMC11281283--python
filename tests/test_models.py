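"""Dataset splitting and the four grid-searched regressors."""

import numpy as np
import pandas as pd
import pytest

from wheatspad.models import DEFAULT_GRIDS, SpadRegressor, split_dataset


def test_split_72_plots_is_58_14():
    train, test = split_dataset(72, seed=0)
    assert len(train) == 58 and len(test) == 14


def test_split_rounds_half_up():
    # 0.2 * 30 = 6 exactly; 0.2 * 17 = 3.4 -> 3; 0.2 * 18 = 3.6 -> 4
    assert len(split_dataset(30, seed=0)[1]) == 6
    assert len(split_dataset(17, seed=0)[1]) == 3
    assert len(split_dataset(18, seed=0)[1]) == 4


def test_split_is_a_partition():
    train, test = split_dataset(72, seed=5)
    assert len(np.intersect1d(train, test)) == 0
    assert sorted(np.concatenate([train, test])) == list(range(72))


def test_split_determinism_and_seed_sensitivity():
    assert np.array_equal(split_dataset(72, seed=3)[0],
                          split_dataset(72, seed=3)[0])
    assert not np.array_equal(split_dataset(72, seed=3)[1],
                              split_dataset(72, seed=4)[1])


def test_split_validation():
    with pytest.raises(ValueError):
        split_dataset(4, folds=5)
    with pytest.raises(ValueError):
        split_dataset(72, train_fraction=1.0)


def _linear_problem(seed=0, n=40, p=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = 40.0 + X @ w
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


def test_ridge_recovers_exact_linear_fit():
    """With a negligible penalty, ridge matches the closed-form fit."""
    X, y = _linear_problem()
    model = SpadRegressor(family="ridge",
                          grid={"model__alpha": [1e-8]}, seed=0).fit(X, y)
    A = np.column_stack([np.ones(len(y)), X.to_numpy()])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    oracle = A @ coef
    assert np.abs(model.predict(X) - oracle).max() < 1e-6
    from wheatspad.metrics import compute_metrics
    assert compute_metrics(y, model.predict(X)).r2 >= 0.999


def test_rf_constant_target_predicts_constant():
    X, _ = _linear_problem()
    y = np.full(len(X), 47.3)
    model = SpadRegressor(family="rf",
                          grid={"model__n_estimators": [50]}, seed=0).fit(X, y)
    assert np.allclose(model.predict(X), 47.3)


@pytest.mark.parametrize("family", ["ridge", "rf", "svr", "bpnn"])
def test_chosen_hyperparameters_within_grid(family):
    grids = {"ridge": {"model__alpha": [0.1, 1.0]},
             "rf": {"model__n_estimators": [50], "model__max_depth": [None, 3]},
             "svr": {"model__C": [1.0, 10.0], "model__gamma": ["scale:1"],
                     "model__epsilon": [0.1]},
             "bpnn": {"model__hidden_layer_sizes": [(8,)],
                      "model__activation": ["relu"]}}
    X, y = _linear_problem(seed=2)
    model = SpadRegressor(family=family, grid=grids[family], seed=1).fit(X, y)
    resolved = model._resolved_grid(X.shape[1])
    for k, val in model.best_params_.items():
        assert val in resolved[k]
    preds = model.predict(X)
    assert np.isfinite(preds).all() and preds.shape == (len(y),)


def test_family_determinism_under_seed():
    X, y = _linear_problem(seed=3)
    for family, grid in [("rf", {"model__n_estimators": [50]}),
                         ("bpnn", {"model__hidden_layer_sizes": [(8,)],
                                   "model__activation": ["relu"]})]:
        p1 = SpadRegressor(family=family, grid=grid, seed=7).fit(X, y).predict(X)
        p2 = SpadRegressor(family=family, grid=grid, seed=7).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


def test_no_test_set_leakage_canary():
    """Corrupting rows the model never saw cannot change its predictions."""
    X, y = _linear_problem(seed=4, n=50)
    train, test = split_dataset(50, seed=0)
    model_a = SpadRegressor(family="ridge", seed=0).fit(X.iloc[train], y[train])
    y_corrupt = y.copy()
    y_corrupt[test] += 1000.0
    model_b = SpadRegressor(family="ridge", seed=0).fit(X.iloc[train],
                                                        y_corrupt[train])
    assert np.array_equal(model_a.predict(X.iloc[test]),
                          model_b.predict(X.iloc[test]))


def test_predict_row_independence_and_single_row():
    X, y = _linear_problem(seed=5)
    model = SpadRegressor(family="ridge", seed=0).fit(X, y)
    perm = np.random.default_rng(0).permutation(len(X))
    assert np.allclose(model.predict(X.iloc[perm]), model.predict(X)[perm])
    single = model.predict(X.iloc[[0]])
    assert single.shape == (1,)


def test_predict_column_mismatch_rejected():
    X, y = _linear_problem()
    model = SpadRegressor(family="ridge", seed=0).fit(X, y)
    bad = X.rename(columns={"f0": "other"})
    with pytest.raises(ValueError):
        model.predict(bad)


def test_fit_validation():
    X, y = _linear_problem(n=10)
    with pytest.raises(ValueError):
        SpadRegressor(family="nope").fit(X, y)
    Xn = X.copy(); Xn.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        SpadRegressor(family="ridge").fit(Xn, y)
    with pytest.raises(ValueError):
        SpadRegressor(family="ridge", grid={}).fit(X, y)
    with pytest.raises(ValueError):
        SpadRegressor(family="svr").fit(X, np.zeros(10))


def test_default_grids_cover_all_families():
    assert set(DEFAULT_GRIDS) == {"ridge", "rf", "svr", "bpnn"}
    assert all(g for g in DEFAULT_GRIDS.values())
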