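"""Shared fixtures: synthetic scenes at several scales, built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wheatspad.design import generate_design, simulate_measured_spad, simulate_true_spad
from wheatspad.pipeline import ExperimentConfig, generate_dataset
from wheatspad.scene import BANDS, MultibandScene, SceneParams, render_scene


def make_mini_design(n_plots: int, plot_w: float = 0.6, plot_h: float = 0.6,
                     nitrogen_rate: float = 240.0,
                     row_spacing: float = 0.25) -> pd.DataFrame:
    """A compact hand-built design (bypasses the 72-plot factorial)."""
    rows = []
    for i in range(n_plots):
        rows.append(dict(
            plot_id=i + 1, experiment=1, variety="YM22",
            nitrogen_rate=nitrogen_rate, method=None, replicate=1,
            plot_width_m=plot_w, plot_height_m=plot_h,
            row_spacing_m=row_spacing, grid_col=i, grid_row=0,
            x0_m=0.2 + i * (plot_w + 0.2), y0_m=0.2))
    return pd.DataFrame(rows)


def make_spad_table(spads) -> pd.DataFrame:
    return pd.DataFrame({"plot_id": np.arange(1, len(spads) + 1),
                         "spad_true": np.asarray(spads, dtype=float)})


def noise_free_params(gsd_cm: float = 2.0, full_cover: bool = True,
                      seed: int = 0) -> SceneParams:
    return SceneParams(base_gsd_cm=gsd_cm, noise_sd=0.0,
                       cover_intercept=1.0 if full_cover else 0.6,
                       cover_slope_per_kg=0.0, seed=seed)


def make_raster_scene(band_arrays: dict[str, np.ndarray],
                      plot_mask: np.ndarray, gsd_cm: float = 1.0) -> MultibandScene:
    """Wrap explicit per-band rasters into a scene (for oracle tests)."""
    H, W = plot_mask.shape
    bands = np.stack([np.asarray(band_arrays[b], dtype=np.float32)
                      for b in BANDS])
    return MultibandScene(bands=bands, plot_mask=plot_mask.astype(np.int32),
                          gsd_cm=gsd_cm, altitude_m=20.0)


@pytest.fixture(scope="session")
def full_design() -> pd.DataFrame:
    return generate_design(seed=7)


@pytest.fixture(scope="session")
def base_scene(full_design) -> MultibandScene:
    """Full 72-plot scene at the 1.06 cm/px baseline."""
    true = simulate_true_spad(full_design, seed=8)
    spad = simulate_measured_spad(true, seed=9)
    return render_scene(full_design, spad, SceneParams(seed=10))


@pytest.fixture(scope="session")
def coarse_dataset():
    """Full 72-plot design + SPAD + scene at a 4 cm/px working resolution."""
    cfg = ExperimentConfig(seed=11, scene=SceneParams(base_gsd_cm=4.0))
    design, spad, scene = generate_dataset(cfg)
    return design, spad, scene


@pytest.fixture(scope="session")
def coarse_scene(coarse_dataset) -> MultibandScene:
    return coarse_dataset[2]
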