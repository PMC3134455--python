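"""Calibration and discrimination metrics for association scans.

Calibration: the genomic inflation factor lambda (median observed Wald
chi-square over the null chi-square-1 median, 0.45493642), a one-sample
Kolmogorov-Smirnov test of p-value uniformity, and QQ-plot data with
pointwise beta order-statistic bounds.  Discrimination: ROC curves and AUC
built by sweeping the significance level alpha, with false positives
defined on scans of truly-null SNPs and true positives on scans of SNPs
carrying a nonzero simulated weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CHI2_1_MEDIAN",
    "genomic_inflation",
    "ks_uniformity",
    "qq_data",
    "roc_auc",
    "evaluate_benchmark",
    "CalibrationReport",
    "RocReport",
]

# median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.45493642


def genomic_inflation(chi2_stats: np.ndarray) -> float:
    """lambda = median(observed chi-square) / chi-square-1 null median.

    Computed from the Wald statistics directly rather than round-tripping
    through p-value tails.  Values near 1 indicate calibrated tests; values
    well above 1 indicate inflation from unmodelled structure.
    """
    stats_arr = np.asarray(chi2_stats, dtype=float)
    stats_arr = stats_arr[np.isfinite(stats_arr)]
    if stats_arr.size == 0:
        raise ValueError("no finite test statistics")
    return float(np.median(stats_arr) / CHI2_1_MEDIAN)


def ks_uniformity(p_values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Uniform(0, 1)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CalibrationReport:
    lambda_gc: float
    ks_statistic: float
    ks_pvalue: float
    n_tests: int
    qq_expected: np.ndarray | None = None
    qq_observed: np.ndarray | None = None
    qq_lower: np.ndarray | None = None
    qq_upper: np.ndarray | None = None


def qq_data(p_values: np.ndarray) -> CalibrationReport:
    """Sorted observed -log10 p against expected quantiles (k - 0.5)/n.

    The pointwise 95% band comes from the Beta(k, n-k+1) distribution of
    the k-th uniform order statistic.  Zeros are clamped to the smallest
    positive float so -log10 stays finite.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    n = p.size
    p = np.clip(np.sort(p), np.finfo(float).tiny, 1.0)
    k = np.arange(1, n + 1)
    expected = (k - 0.5) / n
    lower = stats.beta.ppf(0.025, k, n - k + 1)
    upper = stats.beta.ppf(0.975, k, n - k + 1)
    chi2 = stats.chi2.isf(p, df=1)
    return CalibrationReport(
        lambda_gc=genomic_inflation(chi2),
        ks_statistic=ks_uniformity(p)[0],
        ks_pvalue=ks_uniformity(p)[1],
        n_tests=n,
        qq_expected=-np.log10(expected),
        qq_observed=-np.log10(p),
        qq_lower=-np.log10(upper),
        qq_upper=-np.log10(np.clip(lower, np.finfo(float).tiny, 1.0)),
    )


@dataclass
class RocReport:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(p_null: np.ndarray, p_alt: np.ndarray) -> RocReport:
    """ROC by sweeping the significance level over all distinct p-values.

    At level alpha, FPR is the fraction of null-SNP p-values <= alpha and
    TPR the fraction of causal-SNP p-values <= alpha; AUC is the trapezoid
    integral, which matches the Mann-Whitney pair-counting probability up
    to tie handling.
    """
    p0 = np.asarray(p_null, dtype=float)
    p1 = np.asarray(p_alt, dtype=float)
    if p0.size == 0 or p1.size == 0:
        raise ValueError("both null and alternative p-value sets must be nonempty")
    thr = np.unique(np.concatenate([p0, p1]))
    thr = np.concatenate([[-np.inf], thr, [np.inf]])
    fpr = (p0[None, :] <= thr[:, None]).mean(axis=1)
    tpr = (p1[None, :] <= thr[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocReport(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def evaluate_benchmark(
    p_values_by_beta: Mapping[float, Sequence[float]],
) -> dict[str, Any]:
    """Summarize a scanned benchmark: per-beta AUC plus null calibration.

    ``p_values_by_beta`` maps each simulated SNP weight to the p-values of
    the SNPs generated at that weight.  The beta = 0 entry is the
    false-positive reference and is mandatory.
    """
    if 0.0 not in p_values_by_beta:
        raise ValueError("need beta = 0 runs as the false-positive reference")
    p_null = np.asarray(p_values_by_beta[0.0], dtype=float)
    chi2_null = stats.chi2.isf(np.clip(p_null, np.finfo(float).tiny, 1.0), df=1)
    ks_stat, ks_p = ks_uniformity(p_null)
    report: dict[str, Any] = {
        "lambda_gc": genomic_inflation(chi2_null),
        "ks_statistic": ks_stat,
        "ks_pvalue": ks_p,
        "n_null": int(p_null.size),
        "auc": {},
    }
    for beta in sorted(p_values_by_beta):
        if beta == 0.0:
            continue
        roc = roc_auc(p_null, np.asarray(p_values_by_beta[beta], dtype=float))
        report["auc"][beta] = roc.auc
    return report
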