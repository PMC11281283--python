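"""Synthetic multispectral canopy scenes with a known SPAD forward model.

A scene is a 5-band reflectance raster (B, G, R, RE, NIR) plus an integer
plot-ID mask on the same grid.  Vegetation pixels follow a monotone
SPAD -> reflectance forward model per band,

    rho_b(SPAD) = a_b * exp(-SPAD / k_b) + c_b,

with red/green/blue decreasing in SPAD (chlorophyll absorption) and NIR
dominated by the c_b plateau (negative a_b makes it mildly increasing).
Soil pixels take a fixed bright soil spectrum.  Within each plot,
vegetation membership follows a 25 cm-period planting-row stripe pattern
whose green fraction is the plot's canopy cover, itself a linear function
of the nitrogen rate — reproducing the soil-exposure confound of sparse
low-nitrogen canopies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

BANDS = ("B", "G", "R", "RE", "NIR")
BASE_ALTITUDE_M = 20.0
BASE_GSD_CM = 1.06

_MIN_PLOT_PX = 7  # one full texture window must fit


@dataclass
class SceneParams:
    """Forward-model and rendering parameters.

    Reflectance coefficients are per band; all emitted reflectances lie in
    [0, 1] for SPAD in [0, 99.9].
    """

    base_gsd_cm: float = BASE_GSD_CM
    base_altitude_m: float = BASE_ALTITUDE_M
    soil_spectrum: Mapping[str, float] = field(default_factory=lambda: {
        "B": 0.10, "G": 0.16, "R": 0.22, "RE": 0.26, "NIR": 0.30})
    leaf_a: Mapping[str, float] = field(default_factory=lambda: {
        "B": 0.12, "G": 0.22, "R": 0.30, "RE": 0.18, "NIR": -0.20})
    leaf_k: Mapping[str, float] = field(default_factory=lambda: {
        "B": 30.0, "G": 40.0, "R": 28.0, "RE": 70.0, "NIR": 80.0})
    leaf_c: Mapping[str, float] = field(default_factory=lambda: {
        "B": 0.03, "G": 0.05, "R": 0.025, "RE": 0.16, "NIR": 0.62})
    cover_intercept: float = 0.60
    cover_slope_per_kg: float = 0.0009
    noise_sd: Mapping[str, float] | float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_gsd_cm <= 0:
            raise ValueError("base_gsd_cm must be positive")
        for b, v in self.soil_spectrum.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"soil reflectance for {b} outside [0, 1]")

    def noise_sd_for(self, band: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[band])
        return float(self.noise_sd)

    def leaf_reflectance(self, band: str, spad) -> np.ndarray:
        """Vegetation reflectance in ``band`` at the given SPAD value(s)."""
        a, k, c = self.leaf_a[band], self.leaf_k[band], self.leaf_c[band]
        return a * np.exp(-np.asarray(spad, dtype=float) / k) + c

    def cover_for_nitrogen(self, nitrogen_rate: float) -> float:
        """Canopy cover fraction in [0, 1] for a nitrogen rate in kg/ha."""
        return float(np.clip(
            self.cover_intercept + self.cover_slope_per_kg * nitrogen_rate,
            0.0, 1.0))


@dataclass
class MultibandScene:
    """5-band reflectance raster + plot mask at a stated GSD."""

    bands: np.ndarray        # (5, H, W) float32, band order BANDS
    plot_mask: np.ndarray    # (H, W) int32, 0 = background
    gsd_cm: float
    altitude_m: float

    def __post_init__(self) -> None:
        if self.bands.shape[0] != len(BANDS):
            raise ValueError("expected 5 bands")
        if self.bands.shape[1:] != self.plot_mask.shape:
            raise ValueError("band rasters and mask must share dimensions")

    def band(self, name: str) -> np.ndarray:
        return self.bands[BANDS.index(name)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.plot_mask.shape

    def plot_ids(self) -> np.ndarray:
        ids = np.unique(self.plot_mask)
        return ids[ids > 0]

    # ---- I/O: multiband TIFF pair + JSON sidecar --------------------------

    def save(self, path_prefix: str | Path) -> None:
        """Write ``<prefix>_bands.tif``, ``<prefix>_mask.tif``, ``<prefix>_meta.json``."""
        import tifffile

        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(f"{prefix}_bands.tif",
                         self.bands.astype(np.float32))
        tifffile.imwrite(f"{prefix}_mask.tif",
                         self.plot_mask.astype(np.int32))
        meta = {"bands": list(BANDS), "gsd_cm": self.gsd_cm,
                "altitude_m": self.altitude_m}
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path_prefix: str | Path) -> "MultibandScene":
        import tifffile

        prefix = Path(path_prefix)
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
        return cls(bands=tifffile.imread(f"{prefix}_bands.tif"),
                   plot_mask=tifffile.imread(f"{prefix}_mask.tif"),
                   gsd_cm=float(meta["gsd_cm"]),
                   altitude_m=float(meta["altitude_m"]))


def render_scene(
    design: pd.DataFrame,
    spad_table: pd.DataFrame,
    params: SceneParams | None = None,
) -> MultibandScene:
    """Render the design into a multispectral scene with known ground truth.

    Background (borders and alleys) is bare soil with mask value 0.  Raises
    ``ValueError`` if any plot spans fewer than 7 pixels in either direction
    at the scene GSD.
    """
    params = params or SceneParams()
    gsd_m = params.base_gsd_cm / 100.0
    spad = spad_table.set_index("plot_id")["spad_true"]

    width_m = (design["x0_m"] + design["plot_width_m"]).max() + 0.5
    height_m = (design["y0_m"] + design["plot_height_m"]).max() + 0.5
    W = int(np.ceil(width_m / gsd_m))
    H = int(np.ceil(height_m / gsd_m))

    bands = np.empty((len(BANDS), H, W), dtype=np.float32)
    for bi, b in enumerate(BANDS):
        bands[bi].fill(params.soil_spectrum[b])
    mask = np.zeros((H, W), dtype=np.int32)

    for row in design.to_dict("records"):
        pid = int(row["plot_id"])
        x0 = int(round(row["x0_m"] / gsd_m))
        y0 = int(round(row["y0_m"] / gsd_m))
        w = int(round(row["plot_width_m"] / gsd_m))
        h = int(round(row["plot_height_m"] / gsd_m))
        x1, y1 = min(x0 + w, W), min(y0 + h, H)
        if (x1 - x0) < _MIN_PLOT_PX or (y1 - y0) < _MIN_PLOT_PX:
            raise ValueError(
                f"plot {pid} smaller than a 7x7 window at "
                f"{params.base_gsd_cm} cm/px")
        mask[y0:y1, x0:x1] = pid

        cover = params.cover_for_nitrogen(row["nitrogen_rate"])
        # planting rows: stripes with the design row spacing, green fraction
        # = cover, measured from the plot's top edge
        y_m = (np.arange(y1 - y0) + 0.5) * gsd_m
        period = row["row_spacing_m"]
        veg_row = (y_m % period) / period < cover
        veg = np.broadcast_to(veg_row[:, None], (y1 - y0, x1 - x0))

        s = float(spad.loc[pid])
        for bi, b in enumerate(BANDS):
            leaf_val = params.leaf_reflectance(b, s)
            block = np.where(veg, leaf_val, params.soil_spectrum[b])
            bands[bi, y0:y1, x0:x1] = block

    rng = np.random.default_rng(params.seed)
    for bi, b in enumerate(BANDS):
        sd = params.noise_sd_for(b)
        if sd > 0:
            bands[bi] += rng.normal(0.0, sd, size=(H, W)).astype(np.float32)
    np.clip(bands, 0.0, 1.0, out=bands)

    return MultibandScene(bands=bands, plot_mask=mask,
                          gsd_cm=params.base_gsd_cm,
                          altitude_m=params.base_altitude_m)


def write_plot_polygons(design: pd.DataFrame, path: str | Path) -> None:
    """Write plot footprints as a GeoJSON FeatureCollection (scene meters)."""
    features = []
    for row in design.to_dict("records"):
        x0, y0 = row["x0_m"], row["y0_m"]
        x1, y1 = x0 + row["plot_width_m"], y0 + row["plot_height_m"]
        features.append({
            "type": "Feature",
            "properties": {"plot_id": int(row["plot_id"]),
                           "experiment": int(row["experiment"])},
            "geometry": {"type": "Polygon", "coordinates": [[
                [x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
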