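"""Flight-altitude simulation: GSD scaling and nearest-neighbor degradation.

At fixed optics the ground sampling distance scales linearly with flight
altitude, so imagery captured at a higher altitude is emulated by
nearest-neighbor resampling of the base scene to the coarser GSD.  Nearest
neighbor copies source pixel values verbatim — no mixed pixels are
introduced — which is why the output band value set is always a subset of
the input's.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .scene import BASE_ALTITUDE_M, BASE_GSD_CM, MultibandScene

STUDY_ALTITUDES_M = (20, 40, 60, 80, 100, 120)


@dataclass
class AltitudeSpec:
    base_altitude_m: float = BASE_ALTITUDE_M
    base_gsd_cm: float = BASE_GSD_CM
    target_altitude_m: float = BASE_ALTITUDE_M

    def __post_init__(self) -> None:
        if self.base_altitude_m <= 0 or self.target_altitude_m <= 0:
            raise ValueError("altitudes must be positive")
        if self.base_gsd_cm <= 0:
            raise ValueError("base_gsd_cm must be positive")
        if self.target_altitude_m < self.base_altitude_m:
            raise ValueError("target altitude must be >= base altitude")


def gsd_for_altitude(
    spec: AltitudeSpec | float,
    base_altitude_m: float = BASE_ALTITUDE_M,
    base_gsd_cm: float = BASE_GSD_CM,
    rounded: bool = False,
) -> float:
    """GSD (cm/pixel) at a target altitude; linear in altitude.

    ``rounded=True`` returns the 2-decimal half-up rounding used for
    reporting; internal computation keeps full precision.
    """
    if not isinstance(spec, AltitudeSpec):
        spec = AltitudeSpec(base_altitude_m=base_altitude_m,
                            base_gsd_cm=base_gsd_cm,
                            target_altitude_m=float(spec))
    gsd = spec.base_gsd_cm * spec.target_altitude_m / spec.base_altitude_m
    if rounded:
        return float(Decimal(repr(gsd)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP))
    return gsd


def _nearest_indices(n_out: int, n_in: int, factor: float) -> np.ndarray:
    """Source index for each output pixel (center mapping, ties to smaller)."""
    centers = (np.arange(n_out) + 0.5) * factor - 0.5
    idx = np.ceil(centers - 0.5).astype(np.int64)  # halfway -> smaller index
    return np.clip(idx, 0, n_in - 1)


def resample_nearest(scene: MultibandScene, target_gsd_cm: float) -> MultibandScene:
    """Degrade a scene to a coarser GSD by nearest-neighbor resampling.

    Output dimensions are ``floor(dim * gsd / target_gsd)``; each output
    pixel copies its nearest source pixel (pixel-center mapping, halfway
    ties broken toward the smaller index).  The mask uses the identical
    index mapping.  Upsampling is rejected.
    """
    if target_gsd_cm < scene.gsd_cm:
        raise ValueError("target GSD must be >= scene GSD (no upsampling)")
    factor = target_gsd_cm / scene.gsd_cm
    H, W = scene.shape
    H_out, W_out = int(H / factor), int(W / factor)
    if H_out < 1 or W_out < 1:
        raise ValueError("target GSD too coarse for scene extent")
    iy = _nearest_indices(H_out, H, factor)
    ix = _nearest_indices(W_out, W, factor)
    bands = scene.bands[:, iy[:, None], ix]
    mask = scene.plot_mask[iy[:, None], ix]
    altitude = scene.altitude_m * target_gsd_cm / scene.gsd_cm
    return MultibandScene(bands=np.ascontiguousarray(bands),
                          plot_mask=np.ascontiguousarray(mask),
                          gsd_cm=float(target_gsd_cm), altitude_m=altitude)


def resample_to_altitude(scene: MultibandScene, altitude_m: float) -> MultibandScene:
    """Resample a base scene to the GSD of the given flight altitude."""
    spec = AltitudeSpec(base_altitude_m=scene.altitude_m,
                        base_gsd_cm=scene.gsd_cm,
                        target_altitude_m=altitude_m)
    if altitude_m == scene.altitude_m:
        return scene
    return resample_nearest(scene, gsd_for_altitude(spec))
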