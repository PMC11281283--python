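"""GLCM texture: quantization, co-occurrence, Haralick metrics, aggregation."""

import numpy as np
import pytest

from wheatspad.scene import BANDS
from wheatspad.texture import (GLCMConfig, TEXTURE_FEATURE_NAMES,
                               glcm_for_window, haralick_metrics,
                               quantize_band, texture_features_for_plot,
                               texture_table)

from conftest import make_raster_scene


def brute_force_haralick(P):
    """Independent double-loop reference implementation."""
    n = P.shape[0]
    mean_i = mean_j = 0.0
    for i in range(n):
        for j in range(n):
            mean_i += i * P[i, j]
            mean_j += j * P[i, j]
    var_i = var_j = hom = con = dis = ent = asm = cor_num = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            var_i += (i - mean_i) ** 2 * p
            var_j += (j - mean_j) ** 2 * p
            hom += p / (1.0 + (i - j) ** 2)
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            if p > 0:
                ent -= p * np.log(p)
            asm += p * p
            cor_num += (i - mean_i) * (j - mean_j) * p
    denom = np.sqrt(var_i * var_j)
    cor = cor_num / denom if denom > 0 else 1.0
    return {"mean": mean_i, "variance": var_i, "homogeneity": hom,
            "contrast": con, "dissimilarity": dis, "entropy": ent,
            "secondmoment": asm, "correlation": cor}


def brute_force_glcm(window, offset, levels):
    """Exhaustive ordered-pair enumeration."""
    dx, dy = offset
    H, W = window.shape
    P = np.zeros((levels, levels))
    for y in range(H):
        for x in range(W):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < H and 0 <= x2 < W:
                P[window[y, x], window[y2, x2]] += 1
    return P / P.sum()


# ---- quantization ---------------------------------------------------------

def test_quantize_constant_band_is_level_zero():
    assert (quantize_band(np.full((5, 5), 0.3)) == 0).all()


def test_quantize_endpoints():
    band = np.array([[0.1, 0.9], [0.5, 0.3]])
    q = quantize_band(band, gray_levels=64)
    assert q[0, 0] == 0 and q[0, 1] == 63


def test_quantize_ramp_near_uniform_histogram():
    band = np.linspace(0.0, 1.0, 64 * 64).reshape(64, 64)
    q = quantize_band(band, gray_levels=64)
    counts = np.bincount(q.ravel(), minlength=64)
    assert counts.max() / counts.min() <= 1.05


# ---- co-occurrence matrix -------------------------------------------------

def test_glcm_constant_window_single_cell():
    P = glcm_for_window(np.zeros((7, 7), dtype=int), (2, 2), gray_levels=4)
    assert P[0, 0] == 1.0 and P.sum() == 1.0


def test_glcm_normalizes_to_one():
    rng = np.random.default_rng(0)
    w = rng.integers(0, 8, (7, 7))
    assert glcm_for_window(w, (2, 2), gray_levels=8).sum() == pytest.approx(1.0)


def test_glcm_checkerboard_diagonal_pairs():
    """Offset (1,1) on a checkerboard pairs same-parity cells only."""
    w = np.indices((6, 6)).sum(axis=0) % 2
    P = glcm_for_window(w, (1, 1), gray_levels=2)
    assert P[0, 0] + P[1, 1] == pytest.approx(1.0)
    assert P[0, 1] == 0.0 and P[1, 0] == 0.0


def test_glcm_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    w = rng.integers(0, 6, (7, 7))
    P = glcm_for_window(w, (2, 2), gray_levels=6)
    assert np.allclose(P, brute_force_glcm(w, (2, 2), 6), atol=1e-15)


def test_glcm_offset_too_large_rejected():
    with pytest.raises(ValueError):
        glcm_for_window(np.zeros((3, 3), dtype=int), (5, 5))


# ---- Haralick metrics -----------------------------------------------------

def test_constant_window_metric_conventions():
    P = glcm_for_window(np.full((7, 7), 3), (2, 2), gray_levels=8)
    m = haralick_metrics(P)
    assert m["contrast"] == 0 and m["dissimilarity"] == 0
    assert m["entropy"] == 0 and m["secondmoment"] == 1.0
    assert m["homogeneity"] == 1.0 and m["variance"] == 0
    assert m["correlation"] == 1.0


def test_entropy_of_two_equal_cells_is_ln2():
    P = np.zeros((2, 2)); P[0, 0] = P[1, 1] = 0.5
    assert haralick_metrics(P)["entropy"] == pytest.approx(np.log(2), abs=1e-14)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_brute_force_on_random_windows(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        w = rng.integers(0, 8, (7, 7))
        P = glcm_for_window(w, (2, 2), gray_levels=8)
        ours = haralick_metrics(P)
        ref = brute_force_haralick(P)
        for k in ours:
            assert ours[k] == pytest.approx(ref[k], abs=1e-10), k


def test_metrics_cross_checked_against_skimage():
    """graycoprops agrees on the metrics it shares, on the same matrix."""
    from skimage.feature import graycoprops

    rng = np.random.default_rng(7)
    w = rng.integers(0, 8, (7, 7))
    P = glcm_for_window(w, (2, 2), gray_levels=8)
    ours = haralick_metrics(P)
    P4 = P[:, :, None, None]
    for mine, theirs in [("contrast", "contrast"),
                         ("dissimilarity", "dissimilarity"),
                         ("homogeneity", "homogeneity"),
                         ("correlation", "correlation")]:
        assert ours[mine] == pytest.approx(
            float(graycoprops(P4, theirs)[0, 0]), abs=1e-10)
    assert ours["secondmoment"] == pytest.approx(
        float(graycoprops(P4, "ASM")[0, 0]), abs=1e-10)


def test_gray_level_translation_invariance():
    """Shifting all levels by a constant leaves contrast/dissimilarity fixed."""
    rng = np.random.default_rng(2)
    w = rng.integers(0, 8, (7, 7))
    m1 = haralick_metrics(glcm_for_window(w, (2, 2), gray_levels=16))
    m2 = haralick_metrics(glcm_for_window(w + 5, (2, 2), gray_levels=16))
    for k in ("contrast", "dissimilarity", "entropy", "secondmoment",
              "homogeneity", "variance", "correlation"):
        assert m1[k] == pytest.approx(m2[k], abs=1e-12)
    assert m2["mean"] == pytest.approx(m1["mean"] + 5, abs=1e-12)


# ---- plot aggregation -----------------------------------------------------

def _random_plot_scene(seed, H=30, W=30, margin=2):
    rng = np.random.default_rng(seed)
    mask = np.zeros((H, W), dtype=np.int32)
    mask[margin:H - margin, margin:W - margin] = 1
    bands = {b: rng.uniform(0, 1, (H, W)) for b in BANDS}
    return make_raster_scene(bands, mask), bands, mask


def test_plot_aggregation_matches_sliding_window_oracle():
    scene, bands, mask = _random_plot_scene(seed=4)
    cfg = GLCMConfig(gray_levels=8)
    fast = texture_features_for_plot(scene, 1, cfg)
    from scipy import ndimage
    valid = ndimage.binary_erosion(mask == 1, structure=np.ones((7, 7)),
                                   border_value=0)
    for b in ("R", "NIR"):
        q = quantize_band(scene.band(b), 8)
        acc = {m: [] for m in
               ("mean", "variance", "homogeneity", "contrast",
                "dissimilarity", "entropy", "secondmoment", "correlation")}
        for y, x in zip(*np.nonzero(valid)):
            P = glcm_for_window(q[y - 3:y + 4, x - 3:x + 4], (2, 2),
                                gray_levels=8)
            for k, v in haralick_metrics(P).items():
                acc[k].append(v)
        for k in acc:
            assert fast[f"{b}-{k}"] == pytest.approx(
                np.mean(acc[k]), abs=1e-9), (b, k)


def test_symmetric_mode_matches_per_window_oracle():
    scene, _, mask = _random_plot_scene(seed=5, H=16, W=16)
    cfg = GLCMConfig(gray_levels=8, symmetric=True)
    fast = texture_features_for_plot(scene, 1, cfg)
    from scipy import ndimage
    valid = ndimage.binary_erosion(mask == 1, structure=np.ones((7, 7)),
                                   border_value=0)
    q = quantize_band(scene.band("G"), 8)
    vals = [haralick_metrics(glcm_for_window(
        q[y - 3:y + 4, x - 3:x + 4], (2, 2), gray_levels=8, symmetric=True))
        for y, x in zip(*np.nonzero(valid))]
    for k in vals[0]:
        assert fast[f"G-{k}"] == pytest.approx(
            np.mean([v[k] for v in vals]), abs=1e-9), k


def test_forty_named_features(coarse_scene):
    feats = texture_features_for_plot(coarse_scene, 1)
    assert list(feats) == TEXTURE_FEATURE_NAMES
    assert len(feats) == 40


def test_constant_scene_contrast_zero_energy_one():
    mask = np.zeros((20, 20), dtype=np.int32)
    mask[2:18, 2:18] = 1
    scene = make_raster_scene({b: np.full((20, 20), 0.4) for b in BANDS}, mask)
    feats = texture_features_for_plot(scene, 1)
    for b in ("R", "G", "B", "NIR", "RE"):
        assert feats[f"{b}-contrast"] == 0.0
        assert feats[f"{b}-secondmoment"] == 1.0


def test_plot_without_full_window_rejected():
    mask = np.zeros((10, 10), dtype=np.int32)
    mask[2:6, 2:6] = 1  # 4x4 plot, no 7x7 window fits
    scene = make_raster_scene({b: np.zeros((10, 10)) for b in BANDS}, mask)
    with pytest.raises(ValueError):
        texture_features_for_plot(scene, 1)


def test_glcm_config_validation():
    with pytest.raises(ValueError):
        GLCMConfig(window=6)
    with pytest.raises(ValueError):
        GLCMConfig(gray_levels=1)
    with pytest.raises(ValueError):
        GLCMConfig(offset=(9, 0))
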