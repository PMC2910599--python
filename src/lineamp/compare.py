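"""Two-cohort copy-number disparity analysis.

Given called states per clone per sample for two tumor cohorts, impute
QC-removed entries from genomic neighbours, aggregate clones into regions of
homogeneous state, test each region's gain/neutral/loss distribution between
cohorts with an exact 3x2 Fisher test, correct with Benjamini-Hochberg over
the distinct regions, merge adjacent concordant significant regions, and apply
group-frequency filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .stats import bh_adjust

GAIN, NEUTRAL, LOSS = 1, 0, -1
_STATE_ROWS = (GAIN, NEUTRAL, LOSS)  # row order of the 3x2 table


@dataclass(frozen=True)
class ComparisonConfig:
    imputation_window_bp: int = 10_000_000
    similarity_threshold: float = 0.90
    alpha_adjusted: float = 0.01
    merge_gap_bp: int = 1_000_000
    min_group_frequency: float = 0.20
    min_frequency_difference: float = 0.10

    def __post_init__(self):
        for name in ("similarity_threshold", "min_group_frequency",
                     "min_frequency_difference", "alpha_adjusted"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.imputation_window_bp <= 0 or self.merge_gap_bp <= 0:
            raise ValueError("windows and gaps must be positive")


@dataclass
class StateMatrix:
    """Clones x samples matrix of {-1, 0, +1} states; NaN marks missing."""

    states: np.ndarray            # float (n_clones, n_samples), NaN = missing
    clone_ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    sample_ids: np.ndarray
    cohorts: np.ndarray           # label per sample

    def __post_init__(self):
        n, m = self.states.shape
        if not (len(self.clone_ids) == len(self.chrom) == len(self.start) == len(self.end) == n):
            raise ValueError("clone annotation length mismatch")
        if not (len(self.sample_ids) == len(self.cohorts) == m):
            raise ValueError("sample annotation length mismatch")

    def centers(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def cohort_columns(self, cohort: str) -> np.ndarray:
        cols = np.flatnonzero(self.cohorts == cohort)
        if cols.size == 0:
            raise ValueError(f"cohort {cohort!r} has no samples")
        return cols


@dataclass
class DisparityRegion:
    chrom: str
    start_bp: int
    end_bp: int
    clone_indices: np.ndarray
    table: np.ndarray             # 3x2 counts, rows gain/neutral/loss
    fisher_p: float
    bh_p: float
    direction_state: int          # GAIN or LOSS
    direction_cohort: str         # cohort with the excess
    freq_a: float                 # frequency of direction_state in cohort A
    freq_b: float
    cohort_a: str = ""
    cohort_b: str = ""

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def impute_missing_states(m: StateMatrix, cfg: ComparisonConfig | None = None) -> StateMatrix:
    """Fill missing entries from the nearest non-missing clone per sample.

    Only neighbours on the same chromosome within ``imputation_window_bp`` of
    the clone's centre qualify; an exact distance tie with disagreeing states
    yields neutral. Observed entries are never altered; entries with no
    neighbour in range stay missing.
    """
    cfg = cfg or ComparisonConfig()
    states = m.states.copy()
    centers = m.centers()
    for chrom in dict.fromkeys(m.chrom.tolist()):
        cidx = np.flatnonzero(m.chrom == chrom)
        pos = centers[cidx]
        sub = states[cidx, :]
        for col in range(sub.shape[1]):
            vec = sub[:, col]
            miss = np.flatnonzero(np.isnan(vec))
            obs = np.flatnonzero(~np.isnan(vec))
            if miss.size == 0 or obs.size == 0:
                continue
            for i in miss:
                d = np.abs(pos[obs] - pos[i])
                k = int(np.argmin(d))
                dmin = d[k]
                if dmin > cfg.imputation_window_bp:
                    continue
                nearest = obs[np.abs(d - dmin) < 0.5]  # bp positions: exact ties
                vals = np.unique(vec[nearest])
                sub[i, col] = vals[0] if len(vals) == 1 else NEUTRAL
        states[cidx, :] = sub
    return replace(m, states=states)


def aggregate_regions(m: StateMatrix, cohort: str, cfg: ComparisonConfig | None = None) -> list[tuple[int, int]]:
    """Partition the clone order into maximal runs of state-homogeneous clones.

    A boundary is placed between adjacent clones (same chromosome) whenever
    fewer than ``similarity_threshold`` of the cohort's samples agree in state
    across the pair (pairs with a missing entry are excluded from the
    denominator). Returns half-open clone index ranges covering every clone.
    """
    cfg = cfg or ComparisonConfig()
    cols = m.cohort_columns(cohort)
    sub = m.states[:, cols]
    n = sub.shape[0]
    boundaries = _boundaries(sub, m.chrom, cfg.similarity_threshold)
    return _runs_from_boundaries(n, boundaries)


def _boundaries(sub: np.ndarray, chrom: np.ndarray, threshold: float) -> set[int]:
    n = sub.shape[0]
    out: set[int] = set()
    if n < 2:
        return out
    a, b = sub[:-1, :], sub[1:, :]
    valid = ~(np.isnan(a) | np.isnan(b))
    agree = (a == b) & valid
    nvalid = valid.sum(axis=1)
    nagree = agree.sum(axis=1)
    for i in range(n - 1):
        if chrom[i] != chrom[i + 1]:
            out.add(i + 1)
        elif nvalid[i] > 0 and nagree[i] / nvalid[i] < threshold:
            out.add(i + 1)
    return out


def _runs_from_boundaries(n: int, boundaries: set[int]) -> list[tuple[int, int]]:
    cuts = sorted(b for b in boundaries if 0 < b < n)
    edges = [0] + cuts + [n]
    return list(zip(edges[:-1], edges[1:]))


def fisher_3x2(table) -> float:
    """Exact conditional p-value for a 3x2 contingency table.

    Sums the multivariate hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (the standard r x c Fisher exact definition).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (3, 2):
        raise ValueError("table must be 3x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    N = int(t.sum())
    if N == 0:
        raise ValueError("zero grand total")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    base = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(N + 1)

    def logp(a, b):
        cc = c[0] - a - b
        return base - (gammaln(a + 1) + gammaln(r[0] - a + 1)
                       + gammaln(b + 1) + gammaln(r[1] - b + 1)
                       + gammaln(cc + 1) + gammaln(r[2] - cc + 1))

    a = np.arange(0, min(r[0], c[0]) + 1)
    b = np.arange(0, min(r[1], c[0]) + 1)
    A, B = np.meshgrid(a, b, indexing="ij")
    C = c[0] - A - B
    ok = (C >= 0) & (C <= r[2])
    lp = np.where(ok, logp(A, B), -np.inf)
    lobs = logp(t[0, 0], t[1, 0])
    p = float(np.exp(lp[ok & (lp <= lobs + 1e-10)]).sum())
    return min(p, 1.0)


def _representative_states(sub: np.ndarray) -> np.ndarray:
    """Majority state per sample over the member clones; ties -> neutral.

    Samples with no observed member clone come back NaN.
    """
    n_gain = np.nansum(sub == GAIN, axis=0)
    n_loss = np.nansum(sub == LOSS, axis=0)
    n_neut = np.nansum(sub == NEUTRAL, axis=0)
    n_obs = n_gain + n_loss + n_neut
    out = np.full(sub.shape[1], np.nan)
    top = np.maximum.reduce([n_gain, n_loss, n_neut])
    for j in range(sub.shape[1]):
        if n_obs[j] == 0:
            continue
        winners = [s for s, cnt in ((GAIN, n_gain[j]), (NEUTRAL, n_neut[j]), (LOSS, n_loss[j]))
                   if cnt == top[j]]
        out[j] = winners[0] if len(winners) == 1 else NEUTRAL
    return out


def _count_table(rep_a: np.ndarray, rep_b: np.ndarray) -> np.ndarray:
    table = np.zeros((3, 2), dtype=int)
    for col, rep in enumerate((rep_a, rep_b)):
        for row, state in enumerate(_STATE_ROWS):
            table[row, col] = int(np.nansum(rep == state))
    return table


def _region_stats(m: StateMatrix, lo: int, hi: int, cols_a, cols_b):
    rep_a = _representative_states(m.states[lo:hi, cols_a])
    rep_b = _representative_states(m.states[lo:hi, cols_b])
    table = _count_table(rep_a, rep_b)
    na = np.sum(~np.isnan(rep_a))
    nb = np.sum(~np.isnan(rep_b))
    freqs = {}
    for state, row in ((GAIN, 0), (LOSS, 2)):
        fa = table[row, 0] / na if na else np.nan
        fb = table[row, 1] / nb if nb else np.nan
        freqs[state] = (fa, fb)
    # direction: altered state with the largest absolute frequency difference
    diffs = {s: abs(freqs[s][1] - freqs[s][0]) for s in (GAIN, LOSS)}
    direction_state = max(diffs, key=lambda s: (diffs[s], s))
    fa, fb = freqs[direction_state]
    return table, direction_state, fa, fb


def compare_cohorts(
    m: StateMatrix,
    cohort_a: str,
    cohort_b: str,
    cfg: ComparisonConfig | None = None,
    impute: bool = True,
    return_all: bool = False,
) -> list[DisparityRegion]:
    """Full disparity pipeline between two cohorts.

    Steps: imputation, per-cohort aggregation intersected into a common
    partition, per-region representative state per sample, exact 3x2 Fisher
    test, BH correction over distinct regions, merging of adjacent concordant
    significant regions within ``merge_gap_bp``, and the >20% group-frequency /
    >10% difference filters. With ``return_all`` the unfiltered per-region
    results (after BH, before significance filtering) are returned instead.
    """
    cfg = cfg or ComparisonConfig()
    cols_a = m.cohort_columns(cohort_a)
    cols_b = m.cohort_columns(cohort_b)
    if cols_a.size < 2 or cols_b.size < 2:
        raise ValueError("each cohort needs at least 2 samples")
    if impute:
        m = impute_missing_states(m, cfg)
    sub_ab = m.states[:, np.concatenate([cols_a, cols_b])]
    bounds = (_boundaries(m.states[:, cols_a], m.chrom, cfg.similarity_threshold)
              | _boundaries(m.states[:, cols_b], m.chrom, cfg.similarity_threshold))
    runs = _runs_from_boundaries(sub_ab.shape[0], bounds)

    regions: list[DisparityRegion] = []
    pvals = []
    for lo, hi in runs:
        table, dstate, fa, fb = _region_stats(m, lo, hi, cols_a, cols_b)
        if table.sum() == 0:
            continue
        p = fisher_3x2(table)
        pvals.append(p)
        regions.append(DisparityRegion(
            chrom=str(m.chrom[lo]), start_bp=int(m.start[lo]), end_bp=int(m.end[hi - 1]),
            clone_indices=np.arange(lo, hi), table=table, fisher_p=p, bh_p=np.nan,
            direction_state=dstate,
            direction_cohort=cohort_b if fb > fa else cohort_a,
            freq_a=fa, freq_b=fb, cohort_a=cohort_a, cohort_b=cohort_b,
        ))
    adj = bh_adjust(pvals)
    for reg, q in zip(regions, adj):
        reg.bh_p = float(q)
    if return_all:
        return regions

    kept = [r for r in regions if r.bh_p <= cfg.alpha_adjusted]
    merged = _merge_adjacent(m, kept, cols_a, cols_b, cfg)
    out = []
    for r in merged:
        if max(r.freq_a, r.freq_b) > cfg.min_group_frequency \
                and abs(r.freq_a - r.freq_b) > cfg.min_frequency_difference:
            out.append(r)
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def _merge_adjacent(m, kept, cols_a, cols_b, cfg) -> list[DisparityRegion]:
    kept = sorted(kept, key=lambda r: (r.chrom, r.start_bp))
    out: list[DisparityRegion] = []
    for r in kept:
        if out:
            prev = out[-1]
            if (prev.chrom == r.chrom
                    and r.start_bp - prev.end_bp <= cfg.merge_gap_bp
                    and prev.direction_state == r.direction_state
                    and prev.direction_cohort == r.direction_cohort):
                lo = int(prev.clone_indices[0])
                hi = int(r.clone_indices[-1]) + 1
                table, dstate, fa, fb = _region_stats(m, lo, hi, cols_a, cols_b)
                out[-1] = DisparityRegion(
                    chrom=prev.chrom, start_bp=prev.start_bp, end_bp=r.end_bp,
                    clone_indices=np.arange(lo, hi), table=table,
                    fisher_p=fisher_3x2(table), bh_p=min(prev.bh_p, r.bh_p),
                    direction_state=dstate,
                    direction_cohort=prev.cohort_b if fb > fa else prev.cohort_a,
                    freq_a=fa, freq_b=fb,
                    cohort_a=prev.cohort_a, cohort_b=prev.cohort_b,
                )
                continue
        out.append(r)
    return out


def alteration_frequency(m: StateMatrix, cohort: str) -> dict[str, np.ndarray]:
    """Per-clone gain and loss fractions in a cohort.

    Missing entries are excluded from the denominator; clones with no observed
    sample come back NaN (undefined, not zero).
    """
    cols = m.cohort_columns(cohort)
    sub = m.states[:, cols]
    n_obs = np.sum(~np.isnan(sub), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(n_obs > 0, np.nansum(sub == GAIN, axis=1) / n_obs, np.nan)
        loss = np.where(n_obs > 0, np.nansum(sub == LOSS, axis=1) / n_obs, np.nan)
    return {"gain": gain, "loss": loss, "n_observed": n_obs}
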