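"""SAM-style two-class permutation differential expression.

Implements the unpaired two-class d-statistic with fudge factor s0 and
permutation-based FDR/q-values, used to derive an expression signature from
the extreme expressers of a chosen gene (highest vs lowest tails).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integration import ExpressionMatrix


@dataclass(frozen=True)
class SamConfig:
    n_extreme: int = 10
    n_permutations: int = 1000
    q_threshold: float = 0.05
    s0: float | str = "auto"      # fudge factor; "auto" = percentile CV rule
    seed: int = 0

    def __post_init__(self):
        if self.n_extreme < 2:
            raise ValueError("n_extreme must be >= 2")
        if self.n_permutations < 100:
            raise ValueError("at least 100 permutations needed for stable q-values")


def select_extremes(expr: ExpressionMatrix, gene: str,
                    cfg: SamConfig | None = None) -> tuple[list[str], list[str]]:
    """Top/bottom ``n_extreme`` samples by the gene's brightest probe.

    The probe with the highest mean intensity across all samples represents
    the gene; boundary ties are broken by the stable column order of the
    expression matrix.
    """
    cfg = cfg or SamConfig()
    probes = expr.probe_map.loc[expr.probe_map["gene"] == gene, "probe_id"]
    probes = [p for p in probes if p in expr.values.index]
    if not probes:
        raise ValueError(f"gene {gene!r} has no probes in the matrix")
    best = max(probes, key=lambda p: expr.values.loc[p].mean())
    vals = expr.values.loc[best]
    order = vals.sort_values(ascending=False, kind="stable").index.tolist()
    if len(order) < 2 * cfg.n_extreme:
        raise ValueError("too few samples for the requested tails")
    return order[:cfg.n_extreme], order[-cfg.n_extreme:]


def _d_stats(x: np.ndarray, g1: np.ndarray, g2: np.ndarray, s0: float) -> np.ndarray:
    """Per-gene d = (mean1 - mean2) / (s + s0), unpaired two-class pooled s."""
    n1, n2 = g1.size, g2.size
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    ss1 = ((x[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (m1 - m2) / denom, np.nan)
    return d


def _auto_s0(x: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    """Percentile-grid s0: minimize the coefficient of variation of the
    median absolute deviation of d within s-quantile windows (Tusher rule)."""
    n1, n2 = g1.size, g2.size
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    ss1 = ((x[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    r = m1 - m2
    qs = np.percentile(s, np.arange(0, 101, 5))
    n_bins = min(100, max(2, len(s) // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_cv, best_s0 = np.inf, float(qs[0])
    for cand in qs:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = r / (s + cand)
        mads = []
        for b in range(n_bins):
            db = d[bins == b]
            db = db[np.isfinite(db)]
            if db.size:
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _permuted_groups(rng, g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One label permutation; balanced (half drawn from each original group)
    when the groups have equal even size, uniform otherwise."""
    n1, n2 = g1.size, g2.size
    if n1 == n2 and n1 % 2 == 0:
        h = n1 // 2
        a = rng.permutation(g1)
        b = rng.permutation(g2)
        p1 = np.concatenate([a[:h], b[:h]])
        p2 = np.concatenate([a[h:], b[h:]])
        return p1, p2
    pool = rng.permutation(np.concatenate([g1, g2]))
    return pool[:n1], pool[n1:]


def sam_two_class(
    expr: ExpressionMatrix | pd.DataFrame,
    group1: list[str],
    group2: list[str],
    cfg: SamConfig | None = None,
) -> pd.DataFrame:
    """Two-class unpaired SAM: per-gene d-statistic, estimated FDR and q-value.

    The q-value of a gene is the smallest estimated FDR over all symmetric
    |d| cutoffs that would call it significant; FDR at a cutoff is
    pi0 * (mean permuted count beyond the cutoff) / (observed count), with pi0
    estimated from the fraction of d-statistics inside the permutation
    interquartile range. Deterministic under ``cfg.seed``.
    """
    cfg = cfg or SamConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    cols = list(values.columns)
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    g1 = np.array([cols.index(s) for s in group1])
    g2 = np.array([cols.index(s) for s in group2])
    x = values.to_numpy(dtype=float)

    # canonical group order: swapping the labels negates d and leaves the
    # permutation stream (hence FDR and q) unchanged
    sign = 1.0
    if tuple(g1) > tuple(g2):
        g1, g2, sign = g2, g1, -1.0

    s0 = _auto_s0(x, g1, g2) if cfg.s0 == "auto" else float(cfg.s0)
    d = _d_stats(x, g1, g2, s0)
    finite = np.isfinite(d)

    rng = np.random.default_rng(cfg.seed)
    m = x.shape[0]
    null_counts = np.zeros(m)
    null_pool = []
    abs_d = np.abs(np.where(finite, d, -np.inf))
    for _ in range(cfg.n_permutations):
        p1, p2 = _permuted_groups(rng, g1, g2)
        dp = _d_stats(x, p1, p2, s0)
        dp = dp[np.isfinite(dp)]
        null_pool.append(dp)
        # count of permuted |d| >= each observed |d|
        sorted_abs = np.sort(np.abs(dp))
        null_counts += dp.size - np.searchsorted(sorted_abs, abs_d, side="left")
    expected = null_counts / cfg.n_permutations

    allnull = np.concatenate(null_pool) if null_pool else np.array([])
    if allnull.size:
        q25, q75 = np.percentile(allnull, [25, 75])
        pi0 = min(1.0, float(np.sum((d[finite] > q25) & (d[finite] < q75)))
                  / max(0.5 * finite.sum(), 1.0))
    else:
        pi0 = 1.0

    order = np.argsort(-abs_d, kind="stable")
    sorted_obs = np.sort(abs_d[finite])
    observed_count = finite.sum() - np.searchsorted(sorted_obs, abs_d, side="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(observed_count > 0,
                       np.minimum(1.0, pi0 * expected / observed_count), np.nan)
    # q = running min of FDR from the least extreme |d| upward
    q = np.full(m, np.nan)
    fo = fdr[order]
    qo = np.minimum.accumulate(fo[::-1])[::-1]
    q[order] = qo
    q[~finite] = np.nan

    return pd.DataFrame({"d": sign * d, "s0": s0, "fdr": fdr, "q": q,
                         "pi0": pi0}, index=values.index)
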