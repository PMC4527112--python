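"""Shared statistical primitives for the paired-cohort pipeline.

Every downstream stage (RNA-seq differential expression, spectral-count
proteomics, concordance mining, enrichment screens) builds on the small set
of tools here: Benjamini-Hochberg FDR adjustment, Spearman rank correlation,
Wilcoxon rank-sum testing with an exact small-sample branch, Pearson
residuals of a 2x2 contingency table, Huber robust line fitting, and the
three-way increased/decreased/unchanged classification of differential
expression results.
"""

from __future__ import annotations

import itertools
import math
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as _sps
import statsmodels.api as _sm

__all__ = [
    "DEClass",
    "bh_adjust",
    "spearman",
    "wilcoxon_rank_sum",
    "pearson_residuals",
    "robust_line_fit",
    "classify_de",
]


class DEClass(str, Enum):
    """Three-way differential-expression call for a single feature."""

    INCREASED = "increased"
    DECREASED = "decreased"
    UNCHANGED = "unchanged"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of raw p-values.

    Returns adjusted p-values in the original order.  The classic step-up
    rule is applied: sort ascending, multiply p_(i) by m/i, then enforce
    monotonicity with a cumulative minimum from the largest rank down, and
    clip at 1.

    Raises
    ------
    ValueError
        If any p-value lies outside [0, 1] or is not finite.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return _sps.rankdata(x, method="average")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  A constant input vector has no defined
    rank correlation and raises ``ValueError``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    rx = _midranks(xa)
    ry = _midranks(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------
# rank-sum testing
# ---------------------------------------------------------------------------

EXACT_MAX_N = 12  # combined sample size up to which the exact branch is used


def _ranksum_stat(ranks_a: np.ndarray) -> float:
    return float(np.sum(ranks_a))


def _exact_ranksum_p(values: np.ndarray, n_a: int, observed: float) -> float:
    """Two-sided exact p by enumerating every assignment of group labels.

    Enumerates all C(n, n_a) ways of choosing which observations belong to
    group A, computing the rank-sum for each; ties are handled naturally
    because mid-ranks of the pooled sample are fixed under permutation.
    """
    ranks = _midranks(values)
    n = len(values)
    mean_w = n_a * (n + 1) / 2.0
    dev = abs(observed - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank-sum of sample ``a`` in the
    pooled mid-ranking.  For combined sample sizes up to ``EXACT_MAX_N`` the
    p-value is computed by exhaustive enumeration of label assignments
    (exact even under ties); for larger samples a normal approximation with
    tie correction and continuity correction is used.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size == 0 or bb.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([aa, bb])
    ranks = _midranks(pooled)
    n_a, n_b = aa.size, bb.size
    n = n_a + n_b
    w = _ranksum_stat(ranks[:n_a])
    if n <= EXACT_MAX_N:
        p = _exact_ranksum_p(pooled, n_a, w)
        return w, p
    mean_w = n_a * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = 2.0 * _sps.norm.sf(z)
    return w, float(min(p, 1.0))


def ranksum_z(a: Sequence[float], b: Sequence[float]) -> float:
    """Signed standardized rank-sum statistic of ``a`` versus ``b``.

    Positive values mean sample ``a`` tends to carry higher ranks.  Uses the
    tie-corrected normal standardization without continuity correction so
    that values are comparable across windows/lists of different sizes.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if aa.size == 0 or bb.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([aa, bb])
    ranks = _midranks(pooled)
    n_a, n_b = aa.size, bb.size
    n = n_a + n_b
    w = _ranksum_stat(ranks[:n_a])
    mean_w = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 0.0
    return float((w - mean_w) / math.sqrt(var_w))


# ---------------------------------------------------------------------------
# contingency residuals
# ---------------------------------------------------------------------------

def pearson_residuals(observed: Sequence[Sequence[float]]) -> np.ndarray:
    """Pearson residuals (O - E)/sqrt(E) of a 2x2 contingency table.

    Expected counts derive from independence of the margins; the sum of
    squared residuals equals the (uncorrected) chi-square statistic.
    """
    o = np.asarray(observed, dtype=float)
    if o.shape != (2, 2):
        raise ValueError("observed must be a 2x2 table")
    if np.any(o < 0):
        raise ValueError("counts must be non-negative")
    total = o.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all margins must be positive")
    expected = np.outer(row, col) / total
    return (o - expected) / np.sqrt(expected)


# ---------------------------------------------------------------------------
# robust trend fitting
# ---------------------------------------------------------------------------

HUBER_C = 1.345


def robust_line_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Huber M-estimate of a straight line, returning (slope, intercept, slope_p).

    Fits ``y = intercept + slope * x`` by iteratively reweighted least
    squares with the Huber psi function (tuning constant 1.345, the value
    giving 95% efficiency under Gaussian errors).  The slope p-value comes
    from the robust covariance of the coefficient estimates.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    design = _sm.add_constant(xa)
    # degenerate exact-fit case: the Huber scale estimate collapses to zero
    ols = np.linalg.lstsq(design, ya, rcond=None)
    resid = ya - design @ ols[0]
    if np.max(np.abs(resid)) < 1e-12 * max(1.0, np.max(np.abs(ya))):
        slope = float(ols[0][1])
        return slope, float(ols[0][0]), (0.0 if slope != 0 else 1.0)
    model = _sm.RLM(ya, design, M=_sm.robust.norms.HuberT(t=HUBER_C))
    res = model.fit(maxiter=50, tol=1e-8)
    slope = float(res.params[1])
    intercept = float(res.params[0])
    slope_p = float(res.pvalues[1])
    return slope, intercept, slope_p


# ---------------------------------------------------------------------------
# DE classification
# ---------------------------------------------------------------------------

def classify_de(
    fold_change: float,
    fdr: float,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
) -> DEClass:
    """Classify a feature as increased / decreased / unchanged.

    A feature is *increased* when ``fold_change > fc_up`` and ``fdr < alpha``
    (strict inequalities); *decreased* when ``fold_change < fc_down`` and
    ``fdr < alpha``; otherwise *unchanged*.
    """
    if not np.isfinite(fold_change) or fold_change <= 0:
        raise ValueError("fold change must be positive and finite")
    if not (0 <= fdr <= 1):
        raise ValueError("fdr must lie in [0, 1]")
    if fdr < alpha:
        if fold_change > fc_up:
            return DEClass.INCREASED
        if fold_change < fc_down:
            return DEClass.DECREASED
    return DEClass.UNCHANGED
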