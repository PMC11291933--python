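"""Rank-based effect sizes and multiple-testing helpers.

The screening stage of the framework is deliberately non-parametric:
binary contrasts are summarized by Cliff's delta (with a two-sided
Mann-Whitney rank-sum test for significance) and continuous covariates
by the Spearman rank correlation.  Everything downstream operates on
midranks, so all statistics here are invariant under strictly monotone
transforms of the measurements.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cliffs_delta",
    "mann_whitney_p",
    "spearman_assoc",
    "bh_adjust",
    "rank_transform",
    "is_testable",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def cliffs_delta(a, b) -> float:
    """Cliff's delta between two samples.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (m * n), with tied pairs
    contributing zero.  Computed in O((m+n) log(m+n)) through the
    identity delta = 2*U/(m*n) - 1, where U is the midrank Mann-Whitney
    statistic of ``a`` versus ``b``.  Positive values mean ``a`` tends
    to exceed ``b``; range [-1, 1].
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    m, n = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]), method="average")
    # U = (rank sum of a) - m(m+1)/2 counts pairs a>b, ties as 1/2
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    delta = 2.0 * u / (m * n) - 1.0
    return float(min(1.0, max(-1.0, delta)))


def mann_whitney_p(a, b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value for samples a, b."""
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p.

    Returns ``(nan, nan)`` when either input has zero variance, in which
    case the pair is reported as not testable rather than raising.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone-enforced and capped at 1; raises on values outside [0, 1].
    NaN entries (untestable pairs) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def rank_transform(values) -> np.ndarray:
    """Midranks of ``values`` (average ranks on ties), in [1, n]."""
    values = _as_1d(values, "values")
    return sps.rankdata(values, method="average")


def is_testable(values, group_a, group_b, min_nonzero: int = 3) -> bool:
    """Minimum-information rule for a covariate on a two-group contrast.

    A variable is testable only when it has at least ``min_nonzero``
    nonzero observations in *each* of the two groups being compared;
    sparse covariates (e.g. a drug nobody in one arm received) are
    excluded from the screen rather than tested on no information.
    """
    values = np.asarray(values, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    n_a = np.count_nonzero(values[group_a])
    n_b = np.count_nonzero(values[group_b])
    return bool(n_a >= min_nonzero and n_b >= min_nonzero)
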