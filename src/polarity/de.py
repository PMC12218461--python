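"""Negative-binomial differential expression for genes and bins.

A deliberately small two-group engine: median-of-ratios size factors,
method-of-moments dispersion pooled within conditions with shrinkage
toward the across-feature mean, a Wald-type test on the log2 fold change
with a Student-t reference (df = n - 2, the natural small-sample
correction for triplicate designs), and Benjamini-Hochberg adjustment.
Genes are called differentially expressed at |log2FC| > 1 (exclusive)
with adjusted p <= 0.01; bin families use 0.05.  No outlier filtering,
independent filtering or posterior fold-change shrinkage is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
]

DE_COLUMNS = ["base_mean", "log2fc", "se", "pvalue", "padj", "is_deg"]


@dataclass
class CountMatrix:
    """Raw integer counts (features x samples) with per-sample conditions."""

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        vals = self.counts.values
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def group_columns(self, condition: str) -> list[str]:
        return [c for c in self.counts.columns if self.conditions[c] == condition]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over features with no zero count,
    of the ratio of its count to the feature's geometric mean across
    samples.  When no zero-free feature exists, a pseudo-reference with
    +0.5 on all counts is used instead (with a warning).
    """
    mat = counts.values.astype(float)
    zero_free = np.all(mat > 0, axis=1)
    if not zero_free.any():
        warnings.warn(
            "no feature with all-positive counts; using +0.5 pseudo-reference"
        )
        mat = mat + 0.5
        zero_free = np.ones(mat.shape[0], dtype=bool)
    sub = mat[zero_free]
    log_geomean = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: pd.Series,
    alpha_floor: float = 1e-8,
    shrink: float = 0.2,
) -> pd.Series:
    """Per-feature NB dispersion alpha by method of moments.

    Sample means and variances of normalized counts are pooled within
    conditions (so true fold changes do not inflate the estimate), then
    alpha_i = max((var - mean) / mean^2, alpha_floor).  With ``shrink``
    in (0, 1], each estimate is pulled toward the across-feature mean,
    stabilizing the tiny-replicate estimates.  Features with zero mean
    get NaN and are excluded from testing.
    """
    norm = counts.values / factors.reindex(counts.columns).values
    conds = conditions.reindex(counts.columns).values
    means, variances = [], []
    for cond in pd.unique(conds):
        sub = norm[:, conds == cond]
        means.append(sub.mean(axis=1))
        if sub.shape[1] > 1:
            variances.append(sub.var(axis=1, ddof=1))
    mean_pooled = np.mean(means, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variances:
            var_pooled = np.mean(variances, axis=0)
            alpha = (var_pooled - mean_pooled) / mean_pooled**2
        else:
            alpha = np.full(counts.shape[0], np.nan)
        alpha = np.maximum(alpha, alpha_floor)
    alpha[mean_pooled == 0] = np.nan
    valid = ~np.isnan(alpha)
    if shrink > 0 and valid.sum() > 1:
        trend = alpha[valid].mean()
        alpha[valid] = (1 - shrink) * alpha[valid] + shrink * trend
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are left out of the family."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def wald_test(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    treated: str = "treated",
    control: str = "control",
    pseudocount: float = 0.5,
    lfc_threshold: float = 1.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-group Wald-type test of the log2 fold change per feature.

    The fold change is computed on size-factor-normalized group means
    (with ``pseudocount`` added for stability); its standard error comes
    from the NB variance mean + alpha mean^2 propagated through the log
    by the delta method; the statistic is referred to a Student-t with
    n_treated + n_control - 2 degrees of freedom and BH-adjusted across
    the features actually tested.  Features with all-zero counts are
    dropped before adjustment so the multiple-testing family matches the
    tested features.  A single-replicate group yields a fold change but
    no p-value.
    """
    counts = cm.counts
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, factors, cm.conditions)
    cols_t = cm.group_columns(treated)
    cols_c = cm.group_columns(control)
    if not cols_t or not cols_c:
        raise ValueError(f"need samples in both groups {treated!r} and {control!r}")
    n_t, n_c = len(cols_t), len(cols_c)
    norm = counts / factors.reindex(counts.columns)
    m_t = norm[cols_t].mean(axis=1).values
    m_c = norm[cols_c].mean(axis=1).values
    base_mean = norm.mean(axis=1).values
    log2fc = np.log2((m_t + pseudocount) / (m_c + pseudocount))

    disp = dispersions.reindex(counts.index).values
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = (
            1 / (n_t * np.maximum(m_t, pseudocount))
            + disp / n_t
            + 1 / (n_c * np.maximum(m_c, pseudocount))
            + disp / n_c
        )
    se = np.sqrt(var_log) / np.log(2)

    df_t = n_t + n_c - 2
    testable = (base_mean > 0) & ~np.isnan(disp) & (df_t >= 1)
    if min(n_t, n_c) < 2:
        testable &= False
    pvalue = np.full(len(counts), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue[testable] = 2 * stats.t.sf(np.abs(z[testable]), df=df_t)

    padj = bh_adjust(pvalue)
    is_deg = (np.abs(log2fc) > lfc_threshold) & (padj <= alpha)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "is_deg": np.where(np.isnan(padj), False, is_deg),
        },
        index=counts.index,
    )
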