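"""Split-plot field design and plot-level SPAD simulation.

The emulated trial is a 72-plot winter-wheat experiment: Experiment 1 is a
split-plot factorial of 4 nitrogen rates (main plots) x 4 varieties
(subplots) x 3 replicates = 48 plots; Experiment 2 compares 2 varieties x 4
fertilizer application methods x 3 replicates = 24 plots at a fixed 240
kg/ha nitrogen rate.  Each plot covers 12 m^2 with 25 cm row spacing.

True plot SPAD is an additive treatment model; measured SPAD emulates the
field protocol of a handheld transmittance meter: 5 sampling points x 10
flag leaves x 3 reads per leaf, averaged per plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

EXP1_VARIETIES = ("YM22", "YM25", "YM39", "NM26")
EXP1_NITROGEN_RATES = (0, 150, 240, 330)  # kg/ha
EXP2_VARIETIES = ("YM22", "YM39")
EXP2_METHODS = ("M1", "M2", "M3", "M4")
EXP2_NITROGEN_RATE = 240  # kg/ha

SPAD_MIN, SPAD_MAX = 0.0, 99.9  # meter measurement range, SPAD units

#: columns of the design table
DESIGN_COLUMNS = [
    "plot_id", "experiment", "variety", "nitrogen_rate", "method",
    "replicate", "plot_width_m", "plot_height_m", "row_spacing_m",
    "grid_col", "grid_row", "x0_m", "y0_m",
]


def generate_design(
    seed: int = 0,
    plot_width_m: float = 3.0,
    plot_height_m: float = 4.0,
    row_spacing_m: float = 0.25,
    n_grid_cols: int = 12,
    alley_m: float = 0.5,
    border_m: float = 0.5,
) -> pd.DataFrame:
    """Generate the 72-plot factorial design with a seeded field layout.

    The factorial structure (which treatments exist, with 3 replicates per
    cell) is fixed; the seed only shuffles which physical grid position each
    plot occupies, emulating field randomization.

    Returns a DataFrame with one row per plot and columns
    :data:`DESIGN_COLUMNS`.  ``x0_m``/``y0_m`` are the top-left corner of
    each plot in scene coordinates (meters).
    """
    if plot_width_m <= 0 or plot_height_m <= 0:
        raise ValueError("plot dimensions must be positive")
    rows: list[dict] = []
    pid = 1
    for nrate in EXP1_NITROGEN_RATES:          # main plots: nitrogen
        for variety in EXP1_VARIETIES:         # subplots: variety
            for rep in (1, 2, 3):
                rows.append(dict(
                    plot_id=pid, experiment=1, variety=variety,
                    nitrogen_rate=nrate, method=None, replicate=rep))
                pid += 1
    for variety in EXP2_VARIETIES:             # main plots: variety
        for method in EXP2_METHODS:            # subplots: fertilizer method
            for rep in (1, 2, 3):
                rows.append(dict(
                    plot_id=pid, experiment=2, variety=variety,
                    nitrogen_rate=EXP2_NITROGEN_RATE, method=method,
                    replicate=rep))
                pid += 1
    df = pd.DataFrame(rows)
    df["plot_width_m"] = float(plot_width_m)
    df["plot_height_m"] = float(plot_height_m)
    df["row_spacing_m"] = float(row_spacing_m)

    rng = np.random.default_rng(seed)
    position = rng.permutation(len(df))
    df["grid_col"] = position % n_grid_cols
    df["grid_row"] = position // n_grid_cols
    df["x0_m"] = border_m + df["grid_col"] * (plot_width_m + alley_m)
    df["y0_m"] = border_m + df["grid_row"] * (plot_height_m + alley_m)
    return df[DESIGN_COLUMNS]


def _default_nitrogen_response(nitrogen_rate: float) -> float:
    # linear response spanning 10 SPAD units over the 0-330 kg/ha range
    return 10.0 * nitrogen_rate / 330.0


@dataclass
class SpadEffectParams:
    """Additive treatment model for true plot SPAD.

    spad_true = mu0 + variety offset + method offset + f(N) + N(0, sigma_plot),
    truncated to the 0-99.9 meter range.

    Defaults put the plot-mean SPAD near 49 with a between-plot SD of
    roughly 3-4 SPAD units, a realistic booting-stage nitrogen-trial spread.
    """

    mu0: float = 44.0
    variety_offsets: Mapping[str, float] = field(default_factory=lambda: {
        "YM22": 0.0, "YM25": 1.0, "YM39": 2.0, "NM26": -1.0})
    method_offsets: Mapping[str, float] = field(default_factory=lambda: {
        "M1": 0.0, "M2": 0.8, "M3": 0.4, "M4": 0.6})
    nitrogen_response: Callable[[float], float] = _default_nitrogen_response
    sigma_plot: float = 1.0


def expected_true_spad(design_row: Mapping, params: SpadEffectParams) -> float:
    """Noise-free treatment mean for a single design row."""
    mu = params.mu0
    mu += params.variety_offsets.get(design_row["variety"], 0.0)
    method = design_row.get("method")
    if method is not None and not (isinstance(method, float) and np.isnan(method)):
        mu += params.method_offsets.get(method, 0.0)
    mu += params.nitrogen_response(design_row["nitrogen_rate"])
    return mu


def simulate_true_spad(
    design: pd.DataFrame,
    params: SpadEffectParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw true plot SPAD values from the additive treatment model.

    Returns a DataFrame with ``plot_id`` and ``spad_true`` columns.
    """
    params = params or SpadEffectParams()
    if params.sigma_plot < 0:
        raise ValueError("sigma_plot must be >= 0")
    rng = np.random.default_rng(seed)
    mu = np.array([expected_true_spad(row, params)
                   for row in design.to_dict("records")])
    spad = mu + rng.normal(0.0, params.sigma_plot, size=len(mu)) \
        if params.sigma_plot > 0 else mu.copy()
    spad = np.clip(spad, SPAD_MIN, SPAD_MAX)
    return pd.DataFrame({"plot_id": design["plot_id"].to_numpy(),
                         "spad_true": spad})


@dataclass
class MeasurementProtocol:
    """Field SPAD sampling protocol (five-point method).

    ``meter_sd`` is bounded by the +/-1.0 SPAD-unit accuracy of the
    SPAD-502Plus; ``leaf_sd`` is leaf-to-leaf biological variability.
    """

    points_per_plot: int = 5
    leaves_per_point: int = 10
    reads_per_leaf: int = 3
    leaf_sd: float = 1.5
    meter_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("points_per_plot", "leaves_per_point", "reads_per_leaf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.leaf_sd < 0 or self.meter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.meter_sd > 1.0:
            raise ValueError(
                "meter_sd exceeds the meter's +/-1.0 SPAD-unit accuracy")

    @property
    def n_leaves(self) -> int:
        return self.points_per_plot * self.leaves_per_point


def simulate_measured_spad(
    spad_table: pd.DataFrame,
    protocol: MeasurementProtocol | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the per-plot measured SPAD from the sampling protocol.

    Per leaf: value = spad_true + N(0, leaf_sd); each of the three reads
    adds N(0, meter_sd).  The plot's measured SPAD is the mean over all
    leaves of the per-leaf read means, clipped to the meter range.

    Returns ``plot_id``, ``spad_true``, ``spad_measured``, ``n_leaves``.
    """
    protocol = protocol or MeasurementProtocol()
    rng = np.random.default_rng(seed)
    true = spad_table["spad_true"].to_numpy(dtype=float)
    n_plots = len(true)
    n_leaves, n_reads = protocol.n_leaves, protocol.reads_per_leaf
    leaf = true[:, None] + rng.normal(0.0, protocol.leaf_sd,
                                      size=(n_plots, n_leaves))
    reads = leaf[:, :, None] + rng.normal(0.0, protocol.meter_sd,
                                          size=(n_plots, n_leaves, n_reads))
    measured = np.clip(reads.mean(axis=2).mean(axis=1), SPAD_MIN, SPAD_MAX)
    out = spad_table[["plot_id", "spad_true"]].copy()
    out["spad_measured"] = measured
    out["n_leaves"] = n_leaves
    return out
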