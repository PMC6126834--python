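"""Stratified Q-Q points, conditional fold-enrichment curves, rank tests, π1.

Fold enrichment at a −log10(p) threshold t is the ratio of the fractions of
the annotated set and of the baseline set surviving t (a ratio of
complementary empirical CDFs).  π1 is the Storey estimate of the proportion
of non-null associations, read off a smoothed π0(λ) grid at the largest λ.
Both the rank tests and π1 operate on the full (unpruned) variant set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)


def qq_points(pvals):
    """Expected and observed −log10(p) at rank midpoints.

    Rank i (1 = most significant) is plotted against
    expected_i = −log10((i − 0.5)/n); the expected coordinates depend only
    on n, never on the p-values themselves.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("qq_points needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return expected, observed


@dataclass
class FoldCurve:
    """CDF-ratio fold enrichment over −log10(p) thresholds."""

    thresholds: np.ndarray
    ratio: np.ndarray
    n_numerator: np.ndarray
    n_denominator: np.ndarray
    n_set: int
    n_baseline: int


def fold_enrichment(
    pvals_set,
    pvals_baseline,
    bin_width: float = 0.1,
    min_denominator: int = 10,
    max_threshold: float | None = None,
) -> FoldCurve:
    """Fold enrichment of an annotated set against a baseline set.

    ratio(t) = [#{set: −log10 p ≥ t}/|set|] ÷ [#{baseline: −log10 p ≥ t}/|baseline|].
    Thresholds ascend in steps of ``bin_width`` from 0 and are truncated at
    the largest t at which the baseline still has ≥ ``min_denominator``
    survivors, so the right tail is never a ratio of near-empty counts.
    """
    ps = np.asarray(pvals_set, dtype=float)
    pb = np.asarray(pvals_baseline, dtype=float)
    if ps.size == 0 or pb.size == 0:
        raise ValueError("both the set and the baseline must be nonempty")
    xs = np.sort(-np.log10(ps))
    xb = np.sort(-np.log10(pb))
    top = float(xb.max()) if max_threshold is None else float(max_threshold)
    thresholds = np.arange(0.0, top + bin_width / 2, bin_width)
    # survivors at threshold t: count of x >= t
    n_num = xs.size - np.searchsorted(xs, thresholds, side="left")
    n_den = xb.size - np.searchsorted(xb, thresholds, side="left")
    keep = n_den >= min_denominator
    if keep.any():
        last = np.max(np.nonzero(keep)[0])
        sl = slice(0, last + 1)
    else:
        sl = slice(0, 1)
    thresholds, n_num, n_den = thresholds[sl], n_num[sl], n_den[sl]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (n_num / xs.size) / (n_den / xb.size)
    return FoldCurve(
        thresholds=thresholds,
        ratio=ratio,
        n_numerator=n_num,
        n_denominator=n_den,
        n_set=int(xs.size),
        n_baseline=int(xb.size),
    )


def mann_whitney(sample_a, sample_b, method: str = "auto"):
    """Two-sided Mann-Whitney U comparing two χ² (or any) samples.

    ``method='auto'`` uses exact enumeration when min(n) ≤ 8 and there are
    no ties, otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` with U the statistic of the first
    sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "auto":
        combined = np.concatenate([a, b])
        no_ties = np.unique(combined).size == combined.size
        method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=(method == "asymptotic")
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class Pi1Estimate:
    """Storey estimate of the proportion of non-null hypotheses."""

    pi1: float
    pi0_grid: np.ndarray
    lambda_grid: np.ndarray
    method: str


def estimate_pi1(pvals, lambda_grid=None, method: str = "smoother", fixed_lambda: float = 0.5) -> Pi1Estimate:
    """π1 = 1 − π0 from the Storey π0(λ) grid.

    π0(λ) = #{p > λ} / (n·(1 − λ)).  With ``method='smoother'`` a cubic
    least-squares fit of π0(λ) over the grid is evaluated at the largest λ
    (the limit in which the numerator is dominated by nulls); with
    ``method='fixed'`` the raw π0 at ``fixed_lambda`` is used.  The final π0
    is clamped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("estimate_pi1 needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        warnings.warn(f"estimate_pi1: only {p.size} p-values; estimate will be unstable")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    n = p.size
    ps = np.sort(p)
    tail = n - np.searchsorted(ps, grid, side="right")  # #{p > lambda}
    pi0_grid = tail / (n * (1.0 - grid))
    if method == "smoother":
        coeffs = np.polyfit(grid, pi0_grid, deg=3)
        pi0 = float(np.polyval(coeffs, grid.max()))
    elif method == "fixed":
        idx = int(np.argmin(np.abs(grid - fixed_lambda)))
        pi0 = float(pi0_grid[idx])
    else:
        raise ValueError(f"unknown pi1 method {method!r}")
    pi0 = min(max(pi0, 0.0), 1.0)
    return Pi1Estimate(pi1=1.0 - pi0, pi0_grid=pi0_grid, lambda_grid=grid, method=method)
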