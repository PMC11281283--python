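"""Plot-mean band reflectance and the 22 vegetation indices.

The 22-variable set counts the five raw band reflectances (R, G, B, RE,
NIR) plus 17 derived indices.  Formulas are implemented exactly as used in
the source workflow, including two deliberate departures from common
convention: EVI omits the blue band, OSAVI normalizes by (NIR - R + L),
and NDREI is the red-edge/green normalized difference.  Division by zero
never raises: the affected index is emitted as NaN together with a
per-index error record.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .scene import BANDS, MultibandScene

OSAVI_L = 0.16
WDRVI_A = 0.12

#: the 22 variable names, raw bands first
VI_NAMES = [
    "R", "G", "B", "RE", "NIR",
    "RVI", "GCI", "RECI", "TCARI", "NDVI", "GNDVI", "GRVI", "NDRE",
    "NDREI", "SCCCI", "EVI", "EVI2", "OSAVI", "MCARI",
    "TCARI/OSAVI", "MCARI/OSAVI", "WDRVI",
]

#: the normalized-difference family, bounded in [-1, 1] for nonneg. inputs
NORMALIZED_DIFFERENCE_VIS = ("NDVI", "GNDVI", "GRVI", "NDRE", "NDREI", "WDRVI")


def plot_mean_reflectance(scene: MultibandScene, plot_id: int) -> dict[str, float]:
    """Arithmetic mean reflectance per band over a plot's mask pixels."""
    sel = scene.plot_mask == plot_id
    if not sel.any():
        raise ValueError(f"plot_id {plot_id} not present in mask")
    return {b: float(scene.bands[bi][sel].mean()) for bi, b in enumerate(BANDS)}


def _ratio(num: float, den: float, name: str, errors: dict[str, str]) -> float:
    if den == 0 or not np.isfinite(den) or not np.isfinite(num):
        errors[name] = f"{name}: zero or non-finite denominator"
        return float("nan")
    return num / den


def compute_vis(refl: Mapping[str, float]) -> tuple[dict[str, float], dict[str, str]]:
    """Evaluate the 22 variables from per-band reflectance.

    Returns ``(values, errors)``: ``values`` always has exactly 22 entries
    (NaN where undefined); ``errors`` maps each undefined index to a message.
    """
    R, G, B = float(refl["R"]), float(refl["G"]), float(refl["B"])
    RE, NIR = float(refl["RE"]), float(refl["NIR"])
    for name, v in (("R", R), ("G", G), ("B", B), ("RE", RE), ("NIR", NIR)):
        if not np.isfinite(v):
            raise ValueError(f"band {name} reflectance is not finite")
    errors: dict[str, str] = {}
    v: dict[str, float] = {"R": R, "G": G, "B": B, "RE": RE, "NIR": NIR}

    v["RVI"] = _ratio(NIR, R, "RVI", errors)
    v["GCI"] = _ratio(NIR, G, "GCI", errors) - 1.0
    v["RECI"] = _ratio(NIR, RE, "RECI", errors) - 1.0
    v["TCARI"] = 3.0 * ((RE - R) - 0.2 * (RE - G) * _ratio(RE, R, "TCARI", errors))
    v["NDVI"] = _ratio(NIR - R, NIR + R, "NDVI", errors)
    v["GNDVI"] = _ratio(NIR - G, NIR + G, "GNDVI", errors)
    v["GRVI"] = _ratio(G - R, G + R, "GRVI", errors)
    v["NDRE"] = _ratio(NIR - RE, NIR + RE, "NDRE", errors)
    v["NDREI"] = _ratio(RE - G, RE + G, "NDREI", errors)
    v["SCCCI"] = _ratio(v["NDRE"], v["NDVI"], "SCCCI", errors)
    v["EVI"] = 2.5 * _ratio(NIR - R, 1.0 + NIR - 2.4 * R, "EVI", errors)
    v["EVI2"] = 2.5 * _ratio(NIR - R, NIR + 2.4 * R + 1.0, "EVI2", errors)
    v["OSAVI"] = _ratio(NIR - R, NIR - R + OSAVI_L, "OSAVI", errors)
    v["MCARI"] = ((RE - R) - 0.2 * (RE - G)) * _ratio(RE, R, "MCARI", errors)
    v["TCARI/OSAVI"] = _ratio(v["TCARI"], v["OSAVI"], "TCARI/OSAVI", errors)
    v["MCARI/OSAVI"] = _ratio(v["MCARI"], v["OSAVI"], "MCARI/OSAVI", errors)
    v["WDRVI"] = _ratio(WDRVI_A * NIR - R, WDRVI_A * NIR + R, "WDRVI", errors)

    return {name: v[name] for name in VI_NAMES}, errors


def vi_table(scene: MultibandScene, per_pixel: bool = False) -> pd.DataFrame:
    """One row per plot, columns = the 22 variable names.

    Default computes indices from plot-mean reflectance (mean-then-index);
    ``per_pixel=True`` computes indices per pixel and averages them.
    """
    rows = {}
    for pid in scene.plot_ids():
        if per_pixel:
            sel = scene.plot_mask == pid
            px = {b: scene.bands[bi][sel].astype(float)
                  for bi, b in enumerate(BANDS)}
            n = int(sel.sum())
            acc = np.zeros(len(VI_NAMES))
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = [compute_vis({b: px[b][i] for b in BANDS})[0]
                        for i in range(n)]
            acc = {name: float(np.nanmean([val[name] for val in vals]))
                   for name in VI_NAMES}
            rows[int(pid)] = acc
        else:
            refl = plot_mean_reflectance(scene, int(pid))
            rows[int(pid)] = compute_vis(refl)[0]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=VI_NAMES)
    df.index.name = "plot_id"
    return df


def write_vi_csv(table: pd.DataFrame, path) -> None:
    """CSV with plot_id + 22 columns; non-finite values become empty cells."""
    table.to_csv(path, na_rep="")
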