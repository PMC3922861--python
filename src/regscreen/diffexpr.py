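"""Empirical-Bayes moderated differential-induction calls.

Each (substrate, time) cell is an independent two-group comparison of induced
samples against the uninduced controls at the same time point. Gene-wise
residual variances are shrunk toward a common prior estimated across genes by
moment matching on the log variances (the scaled-F model underlying
empirical-Bayes moderated t-statistics), and calls are made with a two-sided
p-value cutoff plus a log2 fold-change cutoff (defaults P < 0.01, |log2FC| >
0.4, reported as +1 induction / -1 repression / 0 no call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset

DEFAULT_P_CUT = 0.01
DEFAULT_LFC_CUT = 0.4


@dataclass
class ContrastTable:
    """Per-gene, per-(substrate, time) contrast statistics and calls.

    ``table`` is a long frame with columns gene_id, substrate, time_h,
    log2fc, s2, df, t, p, p_bh, call. ``priors`` maps each (substrate,
    time_h) contrast to its fitted prior ``(d0, s0_sq)``; ``d0`` may be
    ``inf`` when the gene-wise variances are consistent with a single common
    variance (the moderated t then becomes the pooled-variance z-like
    statistic).
    """

    table: pd.DataFrame
    priors: dict[tuple[str, float], tuple[float, float]] = field(default_factory=dict)

    def contrasts(self) -> list[tuple[str, float]]:
        return sorted(self.priors)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior (d0, s0_sq) of gene-wise variances.

    Works on log variances: if s2 ~ s0_sq * F(df, d0), then log s2 has mean
    log s0_sq + digamma(df/2) - digamma(d0/2) - log(df/d0) and variance
    trigamma(df/2) + trigamma(d0/2). Genes with zero sample variance are
    floored to the smallest positive variance observed so the estimator
    stays finite.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero; cannot fit a prior")
    s2 = np.where(s2 > 0, s2, positive.min())
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target > 0:
        d0 = 2.0 * trigamma_inverse(target)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: float,
    n_induced: int,
    n_control: int,
    d0: float,
    s0_sq: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p from the posterior variance.

    s2_post = (d0*s0_sq + df*s2) / (d0 + df); t = log2fc / (s_post *
    sqrt(1/n_i + 1/n_c)); p from t with d0 + df degrees of freedom (standard
    normal when d0 is infinite).
    """
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / n_induced + 1.0 / n_control))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    total_df = d0 + df
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return t, np.clip(p, 0.0, 1.0)


def fit_contrasts(data: ExpressionDataset, d0_override: float | None = None) -> ContrastTable:
    """Fit every (substrate, time) induced-vs-control contrast.

    Per gene: log2fc is the difference of group means; s2 the pooled
    two-group residual variance with n_i + n_c - 2 degrees of freedom; the
    prior (d0, s0_sq) is moment-matched across genes per contrast.
    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary pooled two-sample t).

    Contrast cells with fewer than two replicates on either side are
    reported with NaN statistics and call 0, never silently dropped.
    """
    design = data.design
    X = data.matrix
    frames = []
    priors: dict[tuple[str, float], tuple[float, float]] = {}
    for substrate, time_h in data.contrast_cells():
        ind = design[
            (design["role"] == "induced")
            & (design["substrate"] == substrate)
            & (design["time_h"] == time_h)
        ].index
        ctl = design[
            (design["role"] == "control") & (design["time_h"] == time_h)
        ].index
        n_i, n_c = len(ind), len(ctl)
        frame = pd.DataFrame(
            {
                "gene_id": X.index,
                "substrate": substrate,
                "time_h": time_h,
            }
        )
        if n_i < 2 or n_c < 2:
            for col in ("log2fc", "s2", "df", "t", "p", "p_bh"):
                frame[col] = np.nan
            frame["call"] = 0
            frames.append(frame)
            priors[(substrate, time_h)] = (np.nan, np.nan)
            continue
        xi = X[ind].to_numpy()
        xc = X[ctl].to_numpy()
        log2fc = xi.mean(axis=1) - xc.mean(axis=1)
        ss = xi.var(axis=1, ddof=1) * (n_i - 1) + xc.var(axis=1, ddof=1) * (n_c - 1)
        df = n_i + n_c - 2
        s2 = ss / df
        if not np.any(s2 > 0):
            # exact (noise-free) data: any nonzero fold change is certain
            d0, s0_sq = np.inf, 0.0
            nz = log2fc != 0
            t = np.zeros_like(log2fc)
            t[nz] = np.sign(log2fc[nz]) * np.inf
            p = np.where(nz, 0.0, 1.0)
        else:
            if d0_override is not None:
                d0 = float(d0_override)
                s0_sq = float(np.median(s2[s2 > 0]))
            else:
                d0, s0_sq = fit_variance_prior(s2, df)
            t, p = moderated_t(log2fc, s2, df, n_i, n_c, d0, s0_sq)
        # exact nulls: identical groups give fc 0, t 0, p 1 regardless of prior
        frame["log2fc"] = log2fc
        frame["s2"] = s2
        frame["df"] = float(df)
        frame["t"] = t
        frame["p"] = p
        frame["p_bh"] = multipletests(p, method="fdr_bh")[1]
        frame["call"] = 0
        frames.append(frame)
        priors[(substrate, time_h)] = (d0, s0_sq)
    table = pd.concat(frames, ignore_index=True)
    return ContrastTable(table=table, priors=priors)


def call_differential(
    contrasts: ContrastTable,
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Populate +1/-1/0 calls and return per-contrast summary counts.

    A gene is called +1 (induced) when p < p_cut and log2fc > lfc_cut, -1
    (repressed) when p < p_cut and log2fc < -lfc_cut, else 0. Raw p-values
    drive the default call; the Benjamini-Hochberg column is reported for
    users but does not gate.
    """
    if p_cut <= 0 or lfc_cut <= 0:
        raise ValueError("p_cut and lfc_cut must be positive")
    t = contrasts.table
    sig = t["p"] < p_cut
    call = np.zeros(len(t), dtype=int)
    call[(sig & (t["log2fc"] > lfc_cut)).to_numpy()] = 1
    call[(sig & (t["log2fc"] < -lfc_cut)).to_numpy()] = -1
    t["call"] = call
    summary = (
        t.groupby(["substrate", "time_h"])["call"]
        .agg(
            induced=lambda c: int((c == 1).sum()),
            repressed=lambda c: int((c == -1).sum()),
        )
        .reset_index()
    )
    return summary


def induction_breadth(contrasts: ContrastTable) -> pd.Series:
    """Per gene, the number of substrates with a +1 call at >=1 time point."""
    t = contrasts.table
    induced = t[t["call"] == 1]
    breadth = induced.groupby("gene_id")["substrate"].nunique()
    genes = t["gene_id"].unique()
    return breadth.reindex(genes, fill_value=0).astype(int).rename("induction_breadth")
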