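"""Correlation of gene expression with the specific protein production rate.

Across chemostat-like conditions with distinct production rates, genes whose
expression tracks the rate (|r| at or above a threshold, default 0.5) are
flagged as production-associated, with the sign of the correlation recorded.
Pearson correlation is the default; Spearman is available for monotone but
non-linear trends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import RateSeries

DEFAULT_CORR_THRESHOLD = 0.5


def production_correlation(
    series: RateSeries,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene correlation with the production rate and the pass flag.

    Returns a frame indexed by gene with columns ``r`` (NaN for genes with
    zero expression variance), ``passed`` (|r| >= threshold) and ``sign``
    (-1/0/+1). Requires >= 3 conditions with non-constant rates.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    rates = series.rates.to_numpy(dtype=float)
    X = series.expression.to_numpy(dtype=float)
    if method == "spearman":
        rates = stats.rankdata(rates)
        X = np.apply_along_axis(stats.rankdata, 1, X)
    rc = rates - rates.mean()
    xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((rc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ rc) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    passed = np.abs(r) >= threshold
    passed = np.where(np.isnan(r), False, passed)
    sign = np.where(np.isnan(r), 0, np.sign(r)).astype(int)
    return pd.DataFrame(
        {"r": r, "passed": passed.astype(bool), "sign": sign},
        index=series.expression.index,
    )


def pearson_null_tail(threshold: float, n: int) -> float:
    """P(|r| >= threshold) for independent normal vectors of length n.

    Under the null, t = r sqrt((n-2)/(1-r^2)) follows a t distribution with
    n-2 degrees of freedom; used to calibrate the expected false-positive
    rate of the screen at small n.
    """
    if n < 3:
        raise ValueError("Pearson null tail requires n >= 3")
    if threshold >= 1.0:
        return 0.0
    t = threshold * np.sqrt((n - 2) / (1.0 - threshold**2))
    return float(2.0 * stats.t.sf(t, n - 2))
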