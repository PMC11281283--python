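"""Variable-set assembly: VIs, TIs, DWT and their combinations."""

from __future__ import annotations

import logging

import pandas as pd

from .scene import MultibandScene
from .texture import GLCMConfig, texture_table
from .vegindex import vi_table
from .wavelet import wavelet_table

log = logging.getLogger(__name__)

#: the 7 variable-set names, in the study's order
VARIABLE_SETS = ("VIs", "TIs", "DWT", "VIs+TIs", "VIs+DWT", "TIs+DWT",
                 "VIs+TIs+DWT")


def base_feature_tables(
    scene: MultibandScene,
    glcm_config: GLCMConfig | None = None,
    which: tuple[str, ...] = ("VIs", "TIs", "DWT"),
) -> dict[str, pd.DataFrame]:
    """Compute the requested base tables (22 VIs, 40 TIs, 20 DWT)."""
    tables: dict[str, pd.DataFrame] = {}
    if "VIs" in which:
        tables["VIs"] = vi_table(scene)
    if "TIs" in which:
        tables["TIs"] = texture_table(scene, glcm_config)
    if "DWT" in which:
        tables["DWT"] = wavelet_table(scene)
    return tables


def assemble_variable_set(base: dict[str, pd.DataFrame],
                          name: str) -> pd.DataFrame:
    """Column-wise union of the named set's parts, in part order."""
    if name not in VARIABLE_SETS:
        raise ValueError(f"unknown variable set {name!r}")
    parts = name.split("+")
    return pd.concat([base[p] for p in parts], axis=1)


def clean_feature_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns containing non-finite entries (logged), keep the rest."""
    import numpy as np

    finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=0)
    dropped = [c for c, ok in zip(X.columns, finite) if not ok]
    if dropped:
        log.warning("dropping non-finite feature columns: %s", dropped)
    return X.loc[:, X.columns[finite]]
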