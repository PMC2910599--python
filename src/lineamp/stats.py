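"""Shared rank-based statistics used across the pipeline.

One-tailed Mann-Whitney U and Spearman correlation tests with exact small-sample
paths, plus Benjamini-Hochberg adjustment. These wrap scipy/statsmodels; the
module exists so every caller applies the same exactness and tie conventions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

#: combined sample size up to which the exact MWU null distribution is used
EXACT_MWU_MAX_N = 20
#: sample size up to which the exact Spearman permutation null is enumerated
EXACT_SPEARMAN_MAX_N = 7


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (min-cummin form).

    NaN entries are passed through untouched and do not count as tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mwu_one_tailed(x, y, alternative: str = "greater") -> float:
    """One-tailed Mann-Whitney U p-value for ``x`` vs ``y``.

    Exact null distribution when the combined sample size is at most
    ``EXACT_MWU_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections. A probe constant
    across all samples yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = x.size + y.size
    if n <= EXACT_MWU_MAX_N and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    res = _sps.spearmanr(x, y)
    return float(res.statistic)


def spearman_one_tailed(x, y) -> tuple[float, float]:
    """Spearman rho and the one-tailed p-value for a positive correlation.

    For n <= ``EXACT_SPEARMAN_MAX_N`` tie-free pairs the p-value is exact,
    from full enumeration of rank permutations; otherwise the t-distribution
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 4:
        raise ValueError("at least 4 paired samples required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = spearman_rho(x, y)
    n = x.size
    tie_free = not (_has_ties(x) or _has_ties(y))
    if n <= EXACT_SPEARMAN_MAX_N and tie_free:
        rx = _sps.rankdata(x)
        ry = _sps.rankdata(y)
        denom = n * (n * n - 1)
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            d = rx - np.asarray(perm)
            r = 1.0 - 6.0 * float(d @ d) / denom
            if r >= rho - 1e-12:
                count += 1
        return rho, count / total
    res = _sps.spearmanr(x, y, alternative="greater")
    return rho, float(res.pvalue)
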