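"""Expression statistics and copy-number / expression integration.

Implements the cohort differential-expression test, probe-to-gene collapsing,
the windowed Z-score dosage profile, both dosage-association methods (Spearman
correlation on Z-scores; gain/amplification-versus-neutral group test with
median/mean guards), and tumor-versus-normal elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import GAIN, LOSS, NEUTRAL, SampleProfile, SegmentedProfile
from .stats import bh_adjust, mwu_one_tailed, spearman_one_tailed


@dataclass(frozen=True)
class IntegrationConfig:
    window_bp: int = 10_000
    alpha_de: float = 0.01
    alpha_rho: float = 0.01
    alpha_dosage: float = 0.05
    rho_min: float = 0.75
    fold_min: float = 2.0

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        for name in ("alpha_de", "alpha_rho", "alpha_dosage"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with genomic annotation.

    ``values``: DataFrame indexed by probe id, columns sample ids.
    ``probe_map``: DataFrame with columns probe_id, gene, chrom, start, end.
    ``cohorts``: Series mapping sample id to cohort label.
    ``scale``: 'log10', 'log2' or 'linear'.
    """

    values: pd.DataFrame
    probe_map: pd.DataFrame
    cohorts: pd.Series
    scale: str = "log10"

    def __post_init__(self):
        if self.scale not in ("log10", "log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = set(self.values.columns) - set(self.cohorts.index)
        if missing:
            raise ValueError(f"samples without cohort label: {sorted(missing)[:3]}")
        unmapped = set(self.values.index) - set(self.probe_map["probe_id"])
        if unmapped:
            raise ValueError(f"probes without map entry: {sorted(unmapped)[:3]}")

    def samples_in(self, cohort: str) -> list[str]:
        ids = [s for s in self.values.columns if self.cohorts[s] == cohort]
        if not ids:
            raise ValueError(f"cohort {cohort!r} has no samples")
        return ids

    def to_linear(self, arr: np.ndarray) -> np.ndarray:
        if self.scale == "log10":
            return 10.0 ** arr
        if self.scale == "log2":
            return 2.0 ** arr
        return arr


@dataclass
class GeneDosageProfile:
    """Per-sample dosage summaries for one gene.

    ``zscores``: average windowed Z-score over the gene interval per sample.
    ``status``: categorical dosage per sample (+1 gain/amp, 0 neutral, -1 loss),
    reduced from segmentation states of overlapping clones by majority.
    """

    gene: str
    sample_ids: list[str]
    zscores: np.ndarray
    status: np.ndarray


def diff_expression(
    expr: ExpressionMatrix, cohort_a: str, cohort_b: str,
    alternative: str = "B>A",
) -> pd.DataFrame:
    """Per-probe one-tailed Mann-Whitney test between two cohorts.

    ``alternative='B>A'`` tests for higher expression in ``cohort_b``. Returns
    a DataFrame indexed by probe with raw ``p``, BH-adjusted ``p_adj`` over all
    tested probes, and a ``constant`` flag (constant probes get p = 1).
    """
    if alternative not in ("B>A", "A>B"):
        raise ValueError("alternative must be 'B>A' or 'A>B'")
    sa = expr.samples_in(cohort_a)
    sb = expr.samples_in(cohort_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each cohort needs at least 2 samples")
    va = expr.values[sa].to_numpy()
    vb = expr.values[sb].to_numpy()
    ps, const = [], []
    for i in range(va.shape[0]):
        pooled = np.concatenate([va[i], vb[i]])
        is_const = bool(np.all(pooled == pooled[0]))
        const.append(is_const)
        if is_const:
            ps.append(1.0)
        elif alternative == "B>A":
            ps.append(mwu_one_tailed(vb[i], va[i], "greater"))
        else:
            ps.append(mwu_one_tailed(va[i], vb[i], "greater"))
    return pd.DataFrame(
        {"p": ps, "p_adj": bh_adjust(ps), "constant": const},
        index=expr.values.index,
    )


def collapse_probes(
    results: pd.DataFrame, probe_map: pd.DataFrame, rule: str,
    intensity: pd.Series | None = None,
) -> pd.DataFrame:
    """Reduce per-probe results to one record per gene.

    ``rule='min_p'`` keeps the probe with the lowest p-value; ``rule='max_intensity'``
    keeps the probe with the highest mean intensity (supply ``intensity``).
    The chosen probe id is recorded.
    """
    if rule not in ("min_p", "max_intensity"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    gene_of = probe_map.set_index("probe_id")["gene"]
    df = results.copy()
    df["gene"] = gene_of.reindex(df.index)
    if rule == "min_p":
        key = df["p"]
    else:
        if intensity is None:
            raise ValueError("max_intensity rule requires an intensity series")
        key = -intensity.reindex(df.index)
    df["_key"] = key
    chosen = df.sort_values("_key", kind="stable").groupby("gene", sort=True).head(1)
    out = chosen.drop(columns="_key").reset_index(names="probe_id").set_index("gene")
    return out


def windowed_values(profile: SampleProfile, window_bp: int,
                    chrom_length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-weighted moving average of combined log2 ratios over tiling windows.

    Windows of width ``window_bp`` tile the chromosome from position 0. Each
    clone contributes to every window it overlaps, weighted by base-pair
    overlap. Windows with no coverage are NaN. Single-chromosome profiles only.
    Returns (window start positions, window means).
    """
    if len(set(profile.chrom.tolist())) > 1:
        raise ValueError("windowed averaging operates per chromosome")
    length = chrom_length if chrom_length is not None else int(profile.end.max())
    n_win = int(np.ceil(length / window_bp))
    acc = np.zeros(n_win)
    wt = np.zeros(n_win)
    for i in range(profile.n_clones):
        if profile.missing[i] or np.isnan(profile.log2[i]):
            continue
        w0 = int(profile.start[i] // window_bp)
        w1 = int((profile.end[i] - 1) // window_bp)
        for w in range(w0, min(w1, n_win - 1) + 1):
            lo = max(profile.start[i], w * window_bp)
            hi = min(profile.end[i], (w + 1) * window_bp)
            acc[w] += profile.log2[i] * (hi - lo)
            wt[w] += hi - lo
    with np.errstate(invalid="ignore"):
        means = np.where(wt > 0, acc / np.maximum(wt, 1), np.nan)
    return np.arange(n_win) * window_bp, means


def windowed_zscore(profile: SampleProfile, window_bp: int = 10_000,
                    chrom_length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample standardized windowed copy-number signal.

    The windowed means are Z-transformed with the sample's own mean and SD over
    all covered windows. A constant profile has no defined Z-score and raises.
    """
    starts, means = windowed_values(profile, window_bp, chrom_length)
    ok = ~np.isnan(means)
    sd = float(np.std(means[ok]))
    if not ok.any() or sd <= 1e-12:
        raise ValueError(f"sample {profile.sample_id}: zero variance, Z undefined")
    z = (means - float(np.mean(means[ok]))) / sd
    return starts, z


def gene_zscore(window_starts: np.ndarray, z: np.ndarray, window_bp: int,
                start: int, end: int) -> float:
    """Average Z-score of the windows overlapping a gene interval."""
    sel = (window_starts + window_bp > start) & (window_starts < end)
    vals = z[sel]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def gene_status(seg: SegmentedProfile, profile: SampleProfile,
                start: int, end: int) -> int:
    """Dosage status of a gene: majority segmentation state of overlapping clones."""
    sel = (profile.end > start) & (profile.start < end) & ~profile.missing
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return NEUTRAL
    states = seg.states_per_clone(profile.n_clones, profile.missing)[idx]
    states = states[~np.isnan(states)]
    if states.size == 0:
        return NEUTRAL
    counts = {s: int(np.sum(states == s)) for s in (GAIN, NEUTRAL, LOSS)}
    top = max(counts.values())
    winners = [s for s, c in counts.items() if c == top]
    return winners[0] if len(winners) == 1 else NEUTRAL


def dosage_correlation(dosage_z: np.ndarray, expr: np.ndarray) -> tuple[float, float]:
    """Spearman rho between dosage Z-scores and expression, one-tailed for rho > 0.

    Requires at least 4 paired samples.
    """
    dosage_z = np.asarray(dosage_z, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if dosage_z.size < 4:
        raise ValueError("dosage correlation requires >= 4 paired samples")
    return spearman_one_tailed(dosage_z, expr)


def dosage_correlation_table(profiles: dict[str, GeneDosageProfile],
                             expr_by_gene: dict[str, np.ndarray]) -> pd.DataFrame:
    """Spearman dosage correlation per gene with BH adjustment across genes."""
    rows = {}
    for gene, prof in profiles.items():
        rho, p = dosage_correlation(prof.zscores, expr_by_gene[gene])
        rows[gene] = {"rho": rho, "p": p}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class GroupTestResult:
    p: float
    median_higher: bool
    mean_higher: bool
    n_gain: int
    n_neutral: int
    n_loss_excluded: int
    testable: bool = True
    p_adj: float = field(default=np.nan)


def dosage_group_test(expr: np.ndarray, status: np.ndarray) -> GroupTestResult:
    """One-tailed Mann-Whitney test of gain/amplification vs copy-number-neutral.

    Loss-status samples are excluded (their count is reported). If either group
    is empty the gene is flagged not-testable rather than raising.
    """
    expr = np.asarray(expr, dtype=float)
    status = np.asarray(status)
    gain = expr[status == GAIN]
    neut = expr[status == NEUTRAL]
    n_loss = int(np.sum(status == LOSS))
    if gain.size == 0 or neut.size == 0:
        return GroupTestResult(p=np.nan, median_higher=False, mean_higher=False,
                               n_gain=gain.size, n_neutral=neut.size,
                               n_loss_excluded=n_loss, testable=False)
    p = mwu_one_tailed(gain, neut, "greater")
    return GroupTestResult(
        p=p,
        median_higher=bool(np.median(gain) > np.median(neut)),
        mean_higher=bool(np.mean(gain) > np.mean(neut)),
        n_gain=gain.size, n_neutral=neut.size, n_loss_excluded=n_loss,
    )


def tumor_vs_normal(expr: ExpressionMatrix, tumor_values: np.ndarray,
                    normal_values: np.ndarray) -> tuple[float, float]:
    """Fold change (ratio of linear-scale group medians) and one-tailed p.

    The one-tailed Mann-Whitney tests tumor > normal. Non-positive linear
    medians leave the fold undefined (NaN).
    """
    t = expr.to_linear(np.asarray(tumor_values, dtype=float))
    n = expr.to_linear(np.asarray(normal_values, dtype=float))
    if t.size < 2 or n.size < 2:
        raise ValueError("each group needs at least 2 samples")
    mt, mn = float(np.median(t)), float(np.median(n))
    fold = mt / mn if mt > 0 and mn > 0 else float("nan")
    p = mwu_one_tailed(tumor_values, normal_values, "greater")
    return fold, p
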