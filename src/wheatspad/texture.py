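"""GLCM texture features: 8 Haralick metrics x 5 bands = 40 per plot.

Texture is extracted with a 7x7 moving window and a (2, 2) co-occurrence
displacement (+2 columns, +2 rows, non-symmetric counting).  Each band is
first linearly quantized to 64 gray levels over its full range.  For every
pixel whose centered 7x7 window lies entirely inside the plot mask, the
window's co-occurrence matrix is formed from the 25 ordered gray-level
pairs it contains and summarized by the eight standard Haralick metrics;
the plot-level feature is the mean of each metric over those windows.

The windowed aggregation avoids materializing per-window matrices: the
moment-based metrics (mean, variance, homogeneity, contrast,
dissimilarity, correlation) are sliding block sums of per-pair images via
integral images, while entropy and the angular second moment — which need
the pair multiplicities — come from run lengths of the sorted pair codes
of each window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .scene import MultibandScene

#: metric order within a band
TEXTURE_METRICS = ("mean", "variance", "homogeneity", "contrast",
                   "dissimilarity", "entropy", "secondmoment", "correlation")
#: band order for the 40-feature vector
TEXTURE_BANDS = ("R", "G", "B", "NIR", "RE")

TEXTURE_FEATURE_NAMES = [f"{b}-{m}" for b in TEXTURE_BANDS
                         for m in TEXTURE_METRICS]


@dataclass
class GLCMConfig:
    window: int = 7
    offset: tuple[int, int] = (2, 2)   # (dx, dy): +columns, +rows
    gray_levels: int = 64
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        dx, dy = self.offset
        if abs(dx) >= self.window or abs(dy) >= self.window:
            raise ValueError("offset magnitudes must be < window size")


def quantize_band(band: np.ndarray, gray_levels: int = 64) -> np.ndarray:
    """Linear min-max quantization to integer levels [0, gray_levels-1].

    A constant band maps entirely to level 0.
    """
    band = np.asarray(band, dtype=np.float64)
    lo, hi = float(band.min()), float(band.max())
    if hi == lo:
        return np.zeros(band.shape, dtype=np.int32)
    q = np.floor((band - lo) / (hi - lo) * gray_levels).astype(np.int32)
    return np.clip(q, 0, gray_levels - 1)


def glcm_for_window(
    window: np.ndarray,
    offset: tuple[int, int] = (2, 2),
    gray_levels: int | None = None,
    symmetric: bool = False,
) -> np.ndarray:
    """Normalized co-occurrence matrix of one integer window.

    Counts ordered pairs (p, p + offset) inside the window and normalizes
    to sum 1; symmetric mode also counts each transposed pair.
    """
    w = np.asarray(window)
    dx, dy = offset
    H, W = w.shape
    if H - abs(dy) <= 0 or W - abs(dx) <= 0:
        raise ValueError("window admits no valid pair at this offset")
    if gray_levels is None:
        gray_levels = int(w.max()) + 1
    ys = slice(max(0, -dy), H - max(0, dy))
    xs = slice(max(0, -dx), W - max(0, dx))
    i = w[ys, xs].ravel()
    j = w[max(0, dy):H + min(0, dy), max(0, dx):W + min(0, dx)].ravel()
    P = np.zeros((gray_levels, gray_levels), dtype=np.float64)
    np.add.at(P, (i, j), 1.0)
    if symmetric:
        np.add.at(P, (j, i), 1.0)
    total = P.sum()
    return P / total


def haralick_metrics(P: np.ndarray) -> dict[str, float]:
    """The eight Haralick metrics of a normalized co-occurrence matrix.

    Conventions: natural-log entropy with 0*ln(0) := 0; correlation := 1
    when either marginal is degenerate (constant texture is perfectly
    correlated).
    """
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    mean_i = float((i * P).sum())
    mean_j = float((j * P).sum())
    var_i = float(((i - mean_i) ** 2 * P).sum())
    var_j = float(((j - mean_j) ** 2 * P).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    denom = np.sqrt(var_i * var_j)
    if denom > 0:
        correlation = float(((i - mean_i) * (j - mean_j) * P).sum() / denom)
    else:
        correlation = 1.0
    return {
        "mean": mean_i,
        "variance": var_i,
        "homogeneity": float((P / (1.0 + (i - j) ** 2)).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "entropy": entropy,
        "secondmoment": float((P ** 2).sum()),
        "correlation": correlation,
    }


def _block_sums(A: np.ndarray, hy: int, hx: int) -> np.ndarray:
    """Sliding sums over hy x hx blocks at every top-left position."""
    S = np.zeros((A.shape[0] + 1, A.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(A, axis=0), axis=1, out=S[1:, 1:])
    return S[hy:, hx:] - S[:-hy, hx:] - S[hy:, :-hx] + S[:-hy, :-hx]


def _entropy_energy_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window entropy and angular second moment from pair codes.

    ``codes``: (n_windows, n_pairs) integer array.  Uses run lengths of the
    sorted codes: sum(c^2) over runs equals sum over elements of
    (2*position_in_run + 1), and sum(c*ln c) equals the element-wise sum of
    ln(run length).
    """
    n_pairs = codes.shape[1]
    S = np.sort(codes, axis=1)
    idx = np.arange(n_pairs)
    bound_l = np.empty(S.shape, dtype=bool)
    bound_l[:, 0] = True
    bound_l[:, 1:] = S[:, 1:] != S[:, :-1]
    starts = np.where(bound_l, idx, 0)
    last_start = np.maximum.accumulate(starts, axis=1)
    pos = idx - last_start

    bound_r = np.empty(S.shape, dtype=bool)
    bound_r[:, -1] = True
    bound_r[:, :-1] = S[:, 1:] != S[:, :-1]
    ends = np.where(bound_r, idx, n_pairs - 1)
    next_end = np.minimum.accumulate(ends[:, ::-1], axis=1)[:, ::-1]
    run_len = next_end - last_start + 1

    energy = (2.0 * pos + 1.0).sum(axis=1) / n_pairs**2
    entropy = np.log(n_pairs) - np.log(run_len).sum(axis=1) / n_pairs
    return entropy, energy


def _plot_band_texture(
    quantized: np.ndarray,
    plot_sel: np.ndarray,
    config: GLCMConfig,
) -> dict[str, float]:
    """Mean of the 8 windowed metrics over all fully-inside windows."""
    win = config.window
    half = win // 2
    dx, dy = config.offset
    if dx < 0 or dy < 0:
        raise ValueError("windowed aggregation supports nonnegative offsets")
    span_y, span_x = win - abs(dy), win - abs(dx)
    n_pairs = span_y * span_x * (2 if config.symmetric else 1)

    valid = ndimage.binary_erosion(plot_sel, structure=np.ones((win, win)),
                                   border_value=0)
    cy, cx = np.nonzero(valid)
    if cy.size == 0:
        raise ValueError("plot admits no full texture window")

    # crop to the bounding box of contributing windows
    y0, y1 = cy.min() - half, cy.max() + half + 1
    x0, x1 = cx.min() - half, cx.max() + half + 1
    Q = quantized[y0:y1, x0:x1].astype(np.float64)
    ty, tx = cy - half - y0, cx - half - x0  # window top-lefts, crop coords

    H, W = Q.shape
    I = Q[:H - abs(dy), :W - abs(dx)]
    J = Q[abs(dy):, abs(dx):]
    D = I - J

    def sel(block):  # block sums evaluated at the contributing top-lefts
        return _block_sums(block, span_y, span_x)[ty, tx]

    np_dir = span_y * span_x
    s_i, s_j = sel(I), sel(J)
    s_ii, s_jj, s_ij = sel(I * I), sel(J * J), sel(I * J)
    s_d2, s_absd = sel(D * D), sel(np.abs(D))
    s_inv = sel(1.0 / (1.0 + D * D))
    if config.symmetric:
        s_i, s_j = s_i + s_j, s_j + s_i
        s_ii, s_jj = s_ii + s_jj, s_jj + s_ii
        s_ij, s_d2, s_absd, s_inv = 2 * s_ij, 2 * s_d2, 2 * s_absd, 2 * s_inv

    mean_i, mean_j = s_i / n_pairs, s_j / n_pairs
    var_i = np.maximum(s_ii / n_pairs - mean_i**2, 0.0)
    var_j = np.maximum(s_jj / n_pairs - mean_j**2, 0.0)
    cov = s_ij / n_pairs - mean_i * mean_j
    denom = np.sqrt(var_i * var_j)
    correlation = np.where(denom > 0, np.divide(
        cov, denom, out=np.ones_like(cov), where=denom > 0), 1.0)

    codes_img = (I * config.gray_levels + J).astype(np.int32)
    views = sliding_window_view(codes_img, (span_y, span_x))
    codes = views[ty, tx].reshape(cy.size, np_dir)
    if config.symmetric:
        swapped_img = (J * config.gray_levels + I).astype(np.int32)
        sv = sliding_window_view(swapped_img, (span_y, span_x))
        codes = np.concatenate(
            [codes, sv[ty, tx].reshape(cy.size, np_dir)], axis=1)
    entropy, energy = _entropy_energy_from_codes(codes)

    per_window = {
        "mean": mean_i,
        "variance": var_i,
        "homogeneity": s_inv / n_pairs,
        "contrast": s_d2 / n_pairs,
        "dissimilarity": s_absd / n_pairs,
        "entropy": entropy,
        "secondmoment": energy,
        "correlation": correlation,
    }
    return {m: float(per_window[m].mean()) for m in TEXTURE_METRICS}


def texture_features_for_plot(
    scene: MultibandScene,
    plot_id: int,
    config: GLCMConfig | None = None,
    quantized: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """The 40 plot-level texture features (8 metrics x 5 bands).

    Bands are quantized over the full scene raster; ``quantized`` lets a
    caller reuse the quantization across plots.
    """
    config = config or GLCMConfig()
    if quantized is None:
        quantized = {b: quantize_band(scene.band(b), config.gray_levels)
                     for b in TEXTURE_BANDS}
    plot_sel = scene.plot_mask == plot_id
    if not plot_sel.any():
        raise ValueError(f"plot_id {plot_id} not present in mask")
    out: dict[str, float] = {}
    for b in TEXTURE_BANDS:
        metrics = _plot_band_texture(quantized[b], plot_sel, config)
        for m in TEXTURE_METRICS:
            out[f"{b}-{m}"] = metrics[m]
    return out


def texture_table(scene: MultibandScene,
                  config: GLCMConfig | None = None) -> pd.DataFrame:
    """One row per plot, columns = the 40 texture feature names."""
    config = config or GLCMConfig()
    quantized = {b: quantize_band(scene.band(b), config.gray_levels)
                 for b in TEXTURE_BANDS}
    rows = {int(pid): texture_features_for_plot(scene, int(pid), config,
                                                quantized=quantized)
            for pid in scene.plot_ids()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=TEXTURE_FEATURE_NAMES)
    df.index.name = "plot_id"
    return df
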