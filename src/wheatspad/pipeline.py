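"""End-to-end study orchestration on synthetic scenes.

Two experiment grids mirror the study design: the altitude study degrades
the 20 m base scene to each flight altitude and predicts SPAD from the VIs
set; the variable-set study stays at the base altitude and compares the 7
variable sets.  Both share a single seeded 8:2 plot split, re-run RFE per
grid cell on training plots only, fit the requested model families, and
record train/test metrics with full provenance (seed, config hash,
selected features).
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (MeasurementProtocol, SpadEffectParams, generate_design,
                     simulate_measured_spad, simulate_true_spad)
from .features import (VARIABLE_SETS, assemble_variable_set,
                       base_feature_tables, clean_feature_matrix)
from .metrics import compute_metrics
from .models import MODEL_FAMILIES, SpadRegressor, split_dataset
from .resample import STUDY_ALTITUDES_M, resample_to_altitude
from .scene import MultibandScene, SceneParams, render_scene
from .selection import RFESelector
from .texture import GLCMConfig
from .vegindex import vi_table

log = logging.getLogger(__name__)

_METRIC_COLS = ("r2", "r2_printed", "rmse", "rrmse", "rpd")


@dataclass
class ExperimentConfig:
    seed: int = 0
    altitudes_m: tuple = STUDY_ALTITUDES_M
    variable_sets: tuple = VARIABLE_SETS
    models: tuple = MODEL_FAMILIES
    train_fraction: float = 0.8
    folds: int = 5
    selection: str = "argmax"        # 'argmax' | 'one_se' | 'none'
    rfe_trees: int = 100
    resplit_per_cell: bool = False
    scene: SceneParams = field(default_factory=SceneParams)
    effects: SpadEffectParams = field(default_factory=SpadEffectParams)
    protocol: MeasurementProtocol = field(default_factory=MeasurementProtocol)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)

    def __post_init__(self) -> None:
        unknown = set(self.variable_sets) - set(VARIABLE_SETS)
        if unknown:
            raise ValueError(f"unknown variable sets: {sorted(unknown)}")
        unknown = set(self.models) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


def _stable_repr(obj) -> str:
    """Deterministic repr: callables by qualified name, dataclasses by field."""
    if callable(obj) and not isinstance(obj, type):
        return getattr(obj, "__qualname__", repr(obj))
    if hasattr(obj, "__dataclass_fields__"):
        inner = ", ".join(f"{f.name}={_stable_repr(getattr(obj, f.name))}"
                          for f in fields(obj))
        return f"{type(obj).__name__}({inner})"
    if isinstance(obj, dict):
        return "{" + ", ".join(f"{k!r}: {_stable_repr(v)}"
                               for k, v in sorted(obj.items())) + "}"
    if isinstance(obj, (list, tuple)):
        return "(" + ", ".join(_stable_repr(v) for v in obj) + ")"
    return repr(obj)


def config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(_stable_repr(config).encode()).hexdigest()[:12]


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def generate_dataset(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame, MultibandScene]:
    """Design + SPAD tables + rendered base scene from the master seed."""
    s_design, s_true, s_meas, s_scene, *_ = _child_seeds(config.seed)
    design = generate_design(seed=s_design)
    true = simulate_true_spad(design, config.effects, seed=s_true)
    spad = simulate_measured_spad(true, config.protocol, seed=s_meas)
    scene_params = SceneParams(**{**_scene_kwargs(config.scene),
                                  "seed": s_scene})
    scene = render_scene(design, spad, scene_params)
    return design, spad, scene


def _scene_kwargs(params: SceneParams) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(SceneParams)}


def _select_features(X: pd.DataFrame, y: np.ndarray, train: np.ndarray,
                     config: ExperimentConfig, seed: int) -> tuple[list[str], int]:
    if config.selection == "none":
        return list(X.columns), len(X.columns)
    selector = RFESelector(n_trees=config.rfe_trees, folds=config.folds,
                           seed=seed, rule=config.selection)
    selector.fit(X.iloc[train], y[train])
    return selector.selected_features_, selector.optimal_n_


def _fit_and_score(X: pd.DataFrame, y: np.ndarray, train: np.ndarray,
                   test: np.ndarray, family: str, config: ExperimentConfig,
                   seed: int, tags: dict) -> dict:
    model = SpadRegressor(family=family, folds=config.folds, seed=seed)
    model.fit(X.iloc[train], y[train])
    row = dict(tags)
    row["model"] = family
    for part, idx in (("train", train), ("test", test)):
        rec = compute_metrics(y[idx], model.predict(X.iloc[idx]))
        for m in _METRIC_COLS:
            row[f"{m}_{part}"] = getattr(rec, m)
    row["cv_score"] = model.cv_score_
    return row


def _study(config: ExperimentConfig, cells: list[tuple[str, pd.DataFrame]],
           y: np.ndarray, cell_key: str) -> pd.DataFrame:
    """Shared grid loop: per cell, clean -> select -> fit each family."""
    *_, s_split, s_select, s_model = _child_seeds(config.seed, 8)
    n = len(y)
    train, test = split_dataset(n, config.train_fraction, seed=s_split,
                                folds=config.folds)
    chash = config_hash(config)
    rows = []
    for cell_value, X_raw in cells:
        try:
            X = clean_feature_matrix(X_raw)
            if config.resplit_per_cell:
                cell_tag = zlib.crc32(str(cell_value).encode()) % 1000
                train, test = split_dataset(
                    n, config.train_fraction,
                    seed=s_split + cell_tag, folds=config.folds)
            selected, n_sel = _select_features(X, y, train, config, s_select)
            X_sel = X.loc[:, selected]
        except Exception:
            log.exception("cell %s=%r failed during selection; skipped",
                          cell_key, cell_value)
            continue
        for family in config.models:
            tags = {cell_key: cell_value, "n_candidates": X.shape[1],
                    "n_selected": n_sel,
                    "selected_features": "|".join(selected),
                    "seed": config.seed, "config_hash": chash}
            try:
                rows.append(_fit_and_score(X_sel, y, train, test, family,
                                           config, s_model, tags))
            except Exception:
                log.exception("cell %s=%r model=%s failed; skipped",
                              cell_key, cell_value, family)
    lead = [cell_key, "model", "n_candidates", "n_selected"]
    metrics = [f"{m}_{p}" for p in ("train", "test") for m in _METRIC_COLS]
    tail = ["cv_score", "seed", "config_hash", "selected_features"]
    return pd.DataFrame(rows, columns=lead + metrics + tail)


def run_altitude_study(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """VIs-only prediction across flight altitudes (one row per altitude x model)."""
    config = config or ExperimentConfig()
    design, spad, base_scene = generate_dataset(config)
    y = spad.set_index("plot_id")["spad_measured"]
    cells = []
    for altitude in config.altitudes_m:
        scene = resample_to_altitude(base_scene, altitude)
        X = vi_table(scene).sort_index()
        cells.append((altitude, X))
    y_arr = y.loc[cells[0][1].index].to_numpy()
    return _study(config, cells, y_arr, cell_key="altitude_m")


def run_variable_set_study(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Variable-set comparison at the base altitude (one row per set x model)."""
    config = config or ExperimentConfig()
    design, spad, scene = generate_dataset(config)
    y = spad.set_index("plot_id")["spad_measured"]
    needed = sorted({part for name in config.variable_sets
                     for part in name.split("+")})
    base = base_feature_tables(scene, config.glcm, which=tuple(needed))
    base = {k: v.sort_index() for k, v in base.items()}
    cells = [(name, assemble_variable_set(base, name))
             for name in config.variable_sets]
    y_arr = y.loc[cells[0][1].index].to_numpy()
    return _study(config, cells, y_arr, cell_key="variable_set")


def save_study(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def vis_pipeline_run(
    seed: int,
    altitude_m: float = 20.0,
    families: tuple = ("ridge", "svr"),
    permute_labels: bool = False,
    config: ExperimentConfig | None = None,
) -> dict[str, float]:
    """One VIs-set pipeline run at a single altitude; returns test metrics.

    ``permute_labels=True`` shuffles the measured SPAD across plots before
    the split — a no-signal control run of the identical pipeline.
    Returns {family: test R^2} plus 'best' (max over families) and
    'best_rpd'.
    """
    config = config or ExperimentConfig()
    cfg = ExperimentConfig(**{**{f.name: getattr(config, f.name)
                                 for f in fields(ExperimentConfig)},
                              "seed": seed,
                              "altitudes_m": (altitude_m,),
                              "models": tuple(families)})
    design, spad, base_scene = generate_dataset(cfg)
    y = spad.set_index("plot_id")["spad_measured"]
    scene = resample_to_altitude(base_scene, altitude_m)
    X = clean_feature_matrix(vi_table(scene).sort_index())
    y_arr = y.loc[X.index].to_numpy()
    if permute_labels:
        y_arr = np.random.default_rng(seed + 10007).permutation(y_arr)
    *_, s_split, s_select, s_model = _child_seeds(cfg.seed, 8)
    train, test = split_dataset(len(y_arr), cfg.train_fraction,
                                seed=s_split, folds=cfg.folds)
    selected, _ = _select_features(X, y_arr, train, cfg, s_select)
    X_sel = X.loc[:, selected]
    out: dict[str, float] = {}
    best, best_rpd = -np.inf, None
    for family in families:
        model = SpadRegressor(family=family, folds=cfg.folds, seed=s_model)
        model.fit(X_sel.iloc[train], y_arr[train])
        rec = compute_metrics(y_arr[test], model.predict(X_sel.iloc[test]))
        out[family] = rec.r2
        if rec.r2 > best:
            best, best_rpd = rec.r2, rec.rpd
    out["best"] = best
    out["best_rpd"] = float(best_rpd)
    return out
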