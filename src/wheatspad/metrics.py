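"""Prediction-quality metrics: R^2, RMSE, RRMSE, RPD.

Two coefficients of determination are reported.  ``r2`` is the
conventional 1 - SSE/SST and is the headline value.  ``r2_printed`` is the
explained-variance ratio sum(yhat - ybar)^2 / sum(y - ybar)^2 — the form
some agronomy papers print — preserved alongside because the two differ
whenever predictions are biased or shrunk.

RPD follows the chemometric convention: sample standard deviation (n-1
denominator) of the *measured* values divided by RMSE; the residual-SD
variant is available via ``sd_mode="residual"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MetricsRecord:
    r2: float                 # conventional 1 - SSE/SST
    r2_printed: float         # explained-variance ratio
    rmse: float               # SPAD units
    rrmse: float              # fraction of the measured mean
    rpd: float                # SD / RMSE
    n: int
    context: dict = field(default_factory=dict)


def compute_metrics(
    y_measured,
    y_predicted,
    sd_mode: str = "measured",
    ddof: int = 1,
    context: dict | None = None,
) -> MetricsRecord:
    """Compute the four metrics for one (measured, predicted) pair set.

    Raises ``ValueError`` on length mismatch, n < 2, non-finite values,
    zero variance of the measured values, or zero measured mean.  A
    perfect fit (RMSE = 0) reports RPD as +inf with a warning.
    """
    y = np.asarray(y_measured, dtype=float)
    yhat = np.asarray(y_predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("measured and predicted lengths differ")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite values in inputs")
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    if sst == 0:
        raise ValueError("measured values have zero variance; "
                         "R^2 and RPD are undefined")
    if ybar == 0:
        raise ValueError("measured mean is zero; RRMSE is undefined")

    resid = yhat - y
    rmse = float(np.sqrt((resid ** 2).mean()))
    rrmse = rmse / ybar
    r2 = 1.0 - float((resid ** 2).sum()) / sst
    r2_printed = float(((yhat - ybar) ** 2).sum()) / sst

    if sd_mode == "measured":
        sd = float(y.std(ddof=ddof))
    elif sd_mode == "residual":
        sd = float(resid.std(ddof=ddof))
    else:
        raise ValueError("sd_mode must be 'measured' or 'residual'")
    if rmse == 0:
        warnings.warn("RMSE is zero; reporting RPD as +inf", stacklevel=2)
        rpd = float("inf")
    else:
        rpd = sd / rmse
    return MetricsRecord(r2=r2, r2_printed=r2_printed, rmse=rmse,
                         rrmse=rrmse, rpd=rpd, n=n,
                         context=dict(context or {}))
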