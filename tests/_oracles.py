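"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic by direct enumeration, staying
independent of the package's implementations.
"""

import itertools
from math import comb, factorial

import numpy as np


def fisher_3x2_oracle(table) -> float:
    """Exact conditional p by enumerating every table with the observed margins.

    Probability of a table with first column (a, b, c) given margins follows
    the multivariate hypergeometric form C(r0,a) C(r1,b) C(r2,c) / C(N, c0).
    """
    t = np.asarray(table, dtype=int)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    N = t.sum()
    denom = comb(N, c[0])

    def prob(a, b, cc):
        return comb(r[0], a) * comb(r[1], b) * comb(r[2], cc) / denom

    p_obs = prob(t[0, 0], t[1, 0], t[2, 0])
    total = 0.0
    for a in range(r[0] + 1):
        for b in range(r[1] + 1):
            cc = c[0] - a - b
            if 0 <= cc <= r[2]:
                p = prob(a, b, cc)
                if p <= p_obs * (1 + 1e-9):
                    total += p
    return min(total, 1.0)


def mwu_one_tailed_oracle(x, y) -> float:
    """P(X stochastically greater): enumerate every group assignment of the
    pooled values and count statistics at least as extreme as observed."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(1.0 if xi > yi else (0.5 if xi == yi else 0.0)
                   for xi in a for yi in b)

    u_obs = u_stat(x, y)
    idx = range(len(pooled))
    count = total = 0
    for chosen in itertools.combinations(idx, n1):
        rest = [i for i in idx if i not in chosen]
        u = u_stat([pooled[i] for i in chosen], [pooled[i] for i in rest])
        total += 1
        if u >= u_obs - 1e-12:
            count += 1
    return count / total


def spearman_oracle(x, y) -> tuple[float, float]:
    """Rho via the rank-difference formula and the exact one-tailed p from
    enumerating all rank permutations (tie-free input only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    denom = n * (n * n - 1)

    def rho_of(pry):
        d = rx - np.asarray(pry)
        return 1.0 - 6.0 * float(d @ d) / denom

    rho = rho_of(ry)
    count = 0
    for perm in itertools.permutations(ry):
        if rho_of(perm) >= rho - 1e-12:
            count += 1
    return rho, count / factorial(n)


def segmentation_oracle(values, lam):
    """Optimal breakpoints by enumerating every subset of boundary positions."""
    values = np.asarray(values, dtype=float)
    n = len(values)

    def objective(bkps):
        bounds = [0] + list(bkps) + [n]
        sse = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = values[lo:hi]
            sse += float(((seg - seg.mean()) ** 2).sum())
        return sse + lam * len(bkps)

    best, best_obj = [], objective([])
    for k in range(1, n):
        for bkps in itertools.combinations(range(1, n), k):
            obj = objective(bkps)
            if obj < best_obj - 1e-12:
                best, best_obj = list(bkps), obj
    return best, best_obj


def amplification_runs_oracle(values, missing, threshold, min_len):
    """All maximal runs of consecutive, non-missing clones above threshold."""
    n = len(values)
    qual = [(not missing[i]) and values[i] > threshold for i in range(n)]
    runs = []
    i = 0
    while i < n:
        if qual[i]:
            j = i
            while j + 1 < n and qual[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def sam_d_oracle(group1, group2, s0=0.0) -> float:
    """Hand evaluation of the unpaired two-class d-statistic."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    s = np.sqrt((1 / n1 + 1 / n2) * pooled)
    return (a.mean() - b.mean()) / (s + s0)
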