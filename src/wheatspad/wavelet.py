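"""Single-level 2-D discrete wavelet features with the bior 1.3 basis.

One separable analysis level (low/high-pass filtering along rows and
columns followed by dyadic downsampling, symmetric boundary extension)
splits each band into four sub-images: LL (approximation), LH (horizontal
detail), HL (vertical detail) and HH (diagonal detail).  The biorthogonal
1.3 pair has distinct analysis/synthesis filters and admits perfect
reconstruction; its analysis low-pass has DC gain sqrt(2), so a constant
raster of value c yields LL coefficients of exactly 2c and zero detail.

One scalar feature per (band, sub-band) is the mean coefficient over the
plot footprint mapped to the sub-band grid — 4 x 5 = 20 features per plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt

from .scene import MultibandScene

WAVELET = "bior1.3"
SUBBANDS = ("LL", "LH", "HL", "HH")
#: band order for the 20-feature vector
WAVELET_BANDS = ("R", "G", "B", "NIR", "RE")
WAVELET_FEATURE_NAMES = [f"{b}_{s}" for s in SUBBANDS for b in WAVELET_BANDS]

_FILTER_LEN = pywt.Wavelet(WAVELET).dec_len  # 6 taps


def dwt2_single_level(band: np.ndarray,
                      wavelet: str = WAVELET) -> dict[str, np.ndarray]:
    """One 2-D DWT level; returns the four sub-band coefficient rasters."""
    band = np.asarray(band, dtype=np.float64)
    flen = pywt.Wavelet(wavelet).dec_len
    if band.shape[0] < flen or band.shape[1] < flen:
        raise ValueError("raster smaller than the wavelet filter support")
    cA, (cH, cV, cD) = pywt.dwt2(band, wavelet, mode="symmetric")
    return {"LL": cA, "LH": cH, "HL": cV, "HH": cD}


def _subband_mask(mask: np.ndarray, subband_shape: tuple[int, int],
                  flen: int = _FILTER_LEN) -> np.ndarray:
    """Nearest-neighbor map of the plot mask onto the sub-band grid.

    Sub-band index k corresponds to source index 2k shifted by the filter
    group delay (flen/2 - 1 samples with symmetric extension), clipped at
    the raster edge.
    """
    shift = flen // 2 - 1
    iy = np.clip(2 * np.arange(subband_shape[0]) - shift, 0, mask.shape[0] - 1)
    ix = np.clip(2 * np.arange(subband_shape[1]) - shift, 0, mask.shape[1] - 1)
    return mask[iy[:, None], ix]


def wavelet_features_for_plot(
    scene: MultibandScene,
    plot_id: int,
    detail_abs: bool = False,
    subbands: dict[str, dict[str, np.ndarray]] | None = None,
) -> dict[str, float]:
    """The 20 plot-level wavelet features.

    ``detail_abs=True`` averages |coefficient| for the detail sub-bands
    instead of the signed mean.  ``subbands`` lets a caller reuse the
    per-band transforms across plots.
    """
    if subbands is None:
        subbands = {b: dwt2_single_level(scene.band(b))
                    for b in WAVELET_BANDS}
    out: dict[str, float] = {}
    for s in SUBBANDS:
        for b in WAVELET_BANDS:
            coeff = subbands[b][s]
            sel = _subband_mask(scene.plot_mask, coeff.shape) == plot_id
            if not sel.any():
                raise ValueError(
                    f"plot_id {plot_id} vanishes at sub-band resolution")
            vals = coeff[sel]
            if detail_abs and s != "LL":
                vals = np.abs(vals)
            out[f"{b}_{s}"] = float(vals.mean())
    return out


def wavelet_table(scene: MultibandScene,
                  detail_abs: bool = False) -> pd.DataFrame:
    """One row per plot, columns = the 20 wavelet feature names."""
    subbands = {b: dwt2_single_level(scene.band(b)) for b in WAVELET_BANDS}
    rows = {int(pid): wavelet_features_for_plot(
                scene, int(pid), detail_abs=detail_abs, subbands=subbands)
            for pid in scene.plot_ids()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=WAVELET_FEATURE_NAMES)
    df.index.name = "plot_id"
    return df
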