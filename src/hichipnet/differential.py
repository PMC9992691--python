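"""Negative-binomial differential testing and threshold classification.

One Wald-style NB engine serves three feature types: HiChIP loop contact
counts, summed anchor H3K27ac signal, and gene expression counts.  Size
factors come from the median-of-ratios; per-feature dispersions are
method-of-moments estimates shrunk halfway toward a fitted mean-dispersion
trend (a0 + a1/mu) with a floor of 1e-4; the two-sided p-value is the Wald
statistic of the log fold-change against a standard normal.

Classification uses the exact fold-change/significance bands applied
throughout this analysis: the constant/constitutive band is
P > 0.5 and |log2FC| < 0.378512 (log2 1.3), loop gain/loss requires
P < 0.1 and |log2FC| > 0.584963 (log2 1.5), enhancer induction/repression
requires P < 0.1 and |log2FC| > 0.378512, and differential expression uses
BH FDR < 0.05 with a per-contrast fold threshold (2.0 or 1.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-4
TREND_WEIGHT = 0.5
PSEUDO_COUNT = 0.5


@dataclass
class ThresholdSet:
    """The exact classification thresholds, as printed to six decimals."""

    p_change: float = 0.1
    p_constant: float = 0.5
    lfc_constant_band: float = 0.378512  # log2(1.3)
    lfc_loop_change: float = 0.584963  # log2(1.5)
    lfc_enhancer_change: float = 0.378512
    rna_fdr: float = 0.05
    rna_fc: dict = field(default_factory=lambda: {"A_vs_B": 2.0, "WT_vs_KO": 1.3})

    def __post_init__(self):
        assert abs(self.lfc_constant_band - np.log2(1.3)) < 1e-6
        assert abs(self.lfc_loop_change - np.log2(1.5)) < 1e-6


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors; falls back to total-count ratios when no
    feature has all-positive counts."""
    counts = np.asarray(counts, dtype=float)
    pos = (counts > 0).all(axis=1)
    if pos.sum() >= 1:
        logc = np.log(counts[pos])
        logmean = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - logmean, axis=0))
    else:
        tot = counts.sum(axis=0)
        sf = tot / tot.mean() if tot.mean() > 0 else np.ones(counts.shape[1])
    return sf


def _fit_dispersion_trend(alpha_hat: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu, clipped to non-negative."""
    ok = np.isfinite(alpha_hat) & (base_mean > 0)
    if ok.sum() < 3:
        fallback = float(np.nanmean(np.where(ok, alpha_hat, np.nan))) if ok.any() else 0.0
        return np.full(len(base_mean), max(fallback, 0.0))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(base_mean > 0, base_mean, np.inf)
    return trend


def nb_wald(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of condition B over condition A.

    ``counts_a``/``counts_b`` are features x replicates matrices of
    non-negative integers (>= 2 replicates each).  Returns a DataFrame with
    base_mean, log2fc, dispersion, p and an all_zero flag.
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("conditions must share the feature axis")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition")
    if (A < 0).any() or (B < 0).any():
        raise ValueError("counts must be non-negative")
    n_a, n_b = A.shape[1], B.shape[1]
    k = np.hstack([A, B])
    if size_factors is None:
        size_factors = median_of_ratios(k)
    size_factors = np.asarray(size_factors, dtype=float)
    norm = k / size_factors
    na, nb = norm[:, :n_a], norm[:, n_a:]
    mu_a = na.mean(axis=1)
    mu_b = nb.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion per group, averaged
    with np.errstate(divide="ignore", invalid="ignore"):
        ah_a = (na.var(axis=1, ddof=1) - mu_a) / mu_a**2
        ah_b = (nb.var(axis=1, ddof=1) - mu_b) / mu_b**2
    stacked = np.column_stack([ah_a, ah_b])
    valid = np.isfinite(stacked)
    with np.errstate(invalid="ignore"):
        alpha_hat = np.where(valid, stacked, 0.0).sum(axis=1) / np.maximum(valid.sum(axis=1), 1)
    alpha_hat = np.clip(alpha_hat, 0.0, None)
    trend = _fit_dispersion_trend(alpha_hat, base_mean)
    # Shrink halfway toward the trend but never below it: with few replicates
    # the moment estimate carries ~1 df per group, and letting it pull the
    # working dispersion under the trend breaks type-I control (an
    # underestimated dispersion inflates false positives, an overestimated
    # one only costs power).
    shrunk = TREND_WEIGHT * trend + (1 - TREND_WEIGHT) * alpha_hat
    alpha = np.maximum.reduce([trend, shrunk, np.full_like(shrunk, DISPERSION_FLOOR)])

    ln_fc = np.log(mu_b + PSEUDO_COUNT) - np.log(mu_a + PSEUDO_COUNT)
    se = np.sqrt(
        (1.0 / (mu_a + PSEUDO_COUNT) + alpha) / n_a + (1.0 / (mu_b + PSEUDO_COUNT) + alpha) / n_b
    )
    z = ln_fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = k.sum(axis=1) == 0
    log2fc = ln_fc / np.log(2.0)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": alpha,
            "stat": z,
            "p": p,
            "all_zero": all_zero,
        }
    )


def classify_loops(records: pd.DataFrame, thresholds: ThresholdSet | None = None) -> pd.Series:
    """gained / lost / constant / unclassified from (p, log2fc)."""
    t = thresholds or ThresholdSet()
    p = records["p"].to_numpy()
    lfc = records["log2fc"].to_numpy()
    out = np.full(len(records), "unclassified", dtype=object)
    out[(p < t.p_change) & (lfc > t.lfc_loop_change)] = "gained"
    out[(p < t.p_change) & (lfc < -t.lfc_loop_change)] = "lost"
    out[(p > t.p_constant) & (np.abs(lfc) < t.lfc_constant_band)] = "constant"
    return pd.Series(out, index=records.index, name="diff_class")


def classify_enhancer_anchors(records: pd.DataFrame, thresholds: ThresholdSet | None = None) -> pd.Series:
    """inducible / repressed / constitutive / unclassified from (p, log2fc)."""
    t = thresholds or ThresholdSet()
    p = records["p"].to_numpy()
    lfc = records["log2fc"].to_numpy()
    out = np.full(len(records), "unclassified", dtype=object)
    out[(p < t.p_change) & (lfc > t.lfc_enhancer_change)] = "inducible"
    out[(p < t.p_change) & (lfc < -t.lfc_enhancer_change)] = "repressed"
    out[(p > t.p_constant) & (np.abs(lfc) < t.lfc_constant_band)] = "constitutive"
    return pd.Series(out, index=records.index, name="diff_class")


def anchor_h3k27ac_signal(
    anchors: pd.DataFrame, peaks: pd.DataFrame, bin_size: int = 10_000
) -> np.ndarray:
    """Summed peak signal within each anchor's 10-kb interval.

    A peak overlapping two anchors contributes its full signal to both.
    """
    sig = np.zeros(len(anchors))
    for chrom, sub in peaks.groupby("chrom", sort=False):
        m = (anchors["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        starts = anchors.loc[m, "bin"].to_numpy() * bin_size
        ends = starts + bin_size
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        pv = sub["signal"].to_numpy(float)
        overlap = (ps[None, :] < ends[:, None]) & (pe[None, :] > starts[:, None])
        sig[m] = overlap @ pv
    return sig


def differential_expression(
    count_matrix: pd.DataFrame,
    n_a: int,
    n_b: int,
    thresholds: ThresholdSet | None = None,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Gene-level NB Wald test with BH adjustment and DE classification.

    DE requires padj < rna_fdr and |log2fc| > log2(fc_threshold); direction
    is recorded as up / down / unchanged.
    """
    t = thresholds or ThresholdSet()
    A = count_matrix.iloc[:, :n_a].to_numpy()
    B = count_matrix.iloc[:, n_a:n_a + n_b].to_numpy()
    res = nb_wald(A, B)
    res.index = count_matrix.index
    _, padj, _, _ = multipletests(res["p"], method="fdr_bh")
    res["padj"] = padj
    lfc_min = np.log2(fc_threshold)
    is_de = (res["padj"] < t.rna_fdr) & (res["log2fc"].abs() > lfc_min)
    res["is_de"] = is_de
    res["de_class"] = np.where(~is_de, "unchanged", np.where(res["log2fc"] > 0, "up", "down"))
    return res
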