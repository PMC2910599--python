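"""Per-sample aCGH processing.

Replicate quality control, least-squares segmentation into piecewise-constant
copy-number profiles, three-state calling, high-level amplification detection
and group-level amplification scoring.

Coordinates are 0-based half-open throughout; clones are assumed sorted by
(chrom, start) within a profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GAIN, NEUTRAL, LOSS = 1, 0, -1


class EmptyProfileError(ValueError):
    """Raised when quality control removes every clone of a profile."""


@dataclass(frozen=True)
class QCConfig:
    """Replicate-spot quality thresholds.

    Spots whose replicate standard deviation exceeds ``max_replicate_sd`` or
    whose signal-to-noise ratio falls below ``min_snr`` are removed.
    """

    max_replicate_sd: float = 0.075
    min_snr: float = 3.0

    def __post_init__(self):
        if self.max_replicate_sd <= 0 or self.min_snr <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class SegmentationConfig:
    """Penalized least-squares segmentation settings.

    The objective is total within-segment SSE plus a per-breakpoint penalty of
    ``penalty_lambda * penalty_scale``. With ``penalty_scale="auto"`` the scale
    is the per-clone noise variance estimated from successive differences, so
    ``penalty_lambda`` stays a dimensionless smoothness knob; a numeric scale
    (e.g. 1.0) makes the penalty absolute in squared-log2 units. Breakpoints
    per chromosome are capped at ``max_breakpoints_per_chrom``. Segment means
    map to states via ``gain_threshold`` / ``loss_threshold`` (log2 units).
    """

    penalty_lambda: float = 6.75
    max_breakpoints_per_chrom: int = 100
    penalty_scale: float | str = "auto"
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2

    def __post_init__(self):
        if self.max_breakpoints_per_chrom < 0:
            raise ValueError("max_breakpoints_per_chrom must be >= 0")
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise ValueError("need gain_threshold > 0 > loss_threshold")


@dataclass(frozen=True)
class AmplificationConfig:
    """High-level amplification caller settings.

    A region is amplified when at least ``min_consecutive_elements`` consecutive
    non-missing clones exceed ``log2_threshold`` (0.6 for tumors; 0.8 for
    carcinoma-in-situ lesions, which are more cell-heterogeneous).
    """

    log2_threshold: float = 0.6
    min_consecutive_elements: int = 2

    def __post_init__(self):
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be positive")
        if self.min_consecutive_elements < 2:
            raise ValueError("min_consecutive_elements must be >= 2")


@dataclass
class SampleProfile:
    """Ordered clone measurements for one hybridization.

    ``log2`` holds the replicate-combined ratio (mean of passing replicates);
    entries flagged in ``missing`` carry no value (NaN).
    """

    sample_id: str
    clone_ids: np.ndarray          # str, shape (n,)
    chrom: np.ndarray              # str, shape (n,)
    start: np.ndarray              # int bp, shape (n,)
    end: np.ndarray                # int bp, shape (n,)
    log2: np.ndarray               # float, NaN where missing
    missing: np.ndarray            # bool
    replicates: np.ndarray | None = None    # (n, k) raw replicate log2
    replicate_sd: np.ndarray | None = None  # (n,)
    snr: np.ndarray | None = None           # (n,)

    def __post_init__(self):
        n = len(self.clone_ids)
        for name in ("chrom", "start", "end", "log2", "missing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if np.any(self.start >= self.end):
            raise ValueError("clone intervals require start < end")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("clones must be sorted by (chrom, start)")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def centers(self) -> np.ndarray:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_sd: int
    n_removed_snr: int

    @property
    def n_removed(self) -> int:
        # a clone may fail both criteria; counts are criterion-wise
        return self.n_input - self.n_retained

    n_retained: int = 0


@dataclass
class Segment:
    chrom: str
    start_idx: int   # clone index, half-open
    end_idx: int
    mean_log2: float
    state: int


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def states_per_clone(self, n_clones: int, missing: np.ndarray) -> np.ndarray:
        """Per-clone state vector; missing clones are NaN (for imputation)."""
        out = np.full(n_clones, np.nan)
        for seg in self.segments:
            out[seg.start_idx:seg.end_idx] = seg.state
        out[missing] = np.nan
        return out

    def means_per_clone(self, n_clones: int) -> np.ndarray:
        out = np.full(n_clones, np.nan)
        for seg in self.segments:
            out[seg.start_idx:seg.end_idx] = seg.mean_log2
        return out


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start_idx: int  # clone index, half-open
    end_idx: int
    start_bp: int
    end_bp: int
    mean_log2: float


def qc_filter(profile: SampleProfile, qc: QCConfig | None = None) -> tuple[SampleProfile, QCReport]:
    """Mark clones failing replicate-SD or SNR criteria as missing.

    Positions are retained; the combined log2 ratio is recomputed as the mean
    of the replicate values of passing clones. Raises :class:`EmptyProfileError`
    if no clone survives.
    """
    qc = qc or QCConfig()
    if profile.replicate_sd is None or profile.snr is None:
        raise ValueError("replicate statistics required for QC")
    fail_sd = profile.replicate_sd > qc.max_replicate_sd
    fail_snr = profile.snr < qc.min_snr
    fail = fail_sd | fail_snr
    missing = profile.missing | fail
    if missing.all():
        raise EmptyProfileError(f"sample {profile.sample_id}: all clones removed by QC")
    if profile.replicates is not None:
        log2 = profile.replicates.mean(axis=1)
    else:
        log2 = profile.log2.copy()
    log2 = np.where(missing, np.nan, log2)
    out = replace(profile, log2=log2, missing=missing)
    report = QCReport(
        n_input=profile.n_clones,
        n_removed_sd=int(fail_sd.sum()),
        n_removed_snr=int(fail_snr.sum()),
        n_retained=int((~missing).sum()),
    )
    return out, report


def _sse_matrix_terms(values: np.ndarray):
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values * values)])
    return c1, c2


def _penalized_dp(values: np.ndarray, lam: float):
    """Optimal penalized partition of ``values``.

    Minimizes sum of within-segment SSE plus ``lam`` per breakpoint. Returns
    (breakpoint positions in [1, n), objective value).
    """
    n = len(values)
    c1, c2 = _sse_matrix_terms(values)
    f = np.empty(n + 1)
    f[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        i = idx[:j]
        length = j - i
        s = c1[j] - c1[i]
        sse = c2[j] - c2[i] - s * s / length
        cand = f[:j] + sse + np.where(i > 0, lam, 0.0)
        k = int(np.argmin(cand))
        f[j] = cand[k]
        back[j] = k
    bkps = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            bkps.append(i)
        j = i
    return sorted(bkps), float(f[n])


def _capped_dp(values: np.ndarray, lam: float, max_bkps: int):
    """Constrained DP: at most ``max_bkps`` breakpoints. O(n^2 k) fallback."""
    n = len(values)
    c1, c2 = _sse_matrix_terms(values)

    def sse(i, j):
        s = c1[j] - c1[i]
        return c2[j] - c2[i] - s * s / (j - i)

    INF = float("inf")
    # f[k][j]: best cost of prefix j using exactly k+1 segments
    nk = max_bkps + 1
    f = np.full((nk, n + 1), INF)
    back = np.zeros((nk, n + 1), dtype=int)
    for j in range(1, n + 1):
        f[0, j] = sse(0, j)
    for k in range(1, nk):
        for j in range(k + 1, n + 1):
            best, arg = INF, k
            for i in range(k, j):
                c = f[k - 1, i] + sse(i, j) + lam
                if c < best:
                    best, arg = c, i
            f[k, j] = best
            back[k, j] = arg
    k = int(np.argmin(f[:, n]))
    bkps = []
    j = n
    kk = k
    while kk > 0:
        i = back[kk, j]
        bkps.append(i)
        j = i
        kk -= 1
    return sorted(bkps), float(f[k, n])


def _noise_variance(values: np.ndarray) -> float:
    """Robust per-clone noise variance from successive differences (MAD rule)."""
    if len(values) < 3:
        return float(np.var(values))
    d = np.diff(values)
    sigma = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)
    return sigma * sigma


def segment_values(values: np.ndarray, cfg: SegmentationConfig) -> list[int]:
    """Breakpoint positions (half-open boundaries in [1, n)) for a 1-D signal."""
    if len(values) == 0:
        return []
    scale = _noise_variance(values) if cfg.penalty_scale == "auto" else float(cfg.penalty_scale)
    lam = cfg.penalty_lambda * scale
    bkps, _ = _penalized_dp(values, lam)
    if len(bkps) > cfg.max_breakpoints_per_chrom:
        bkps, _ = _capped_dp(values, lam, cfg.max_breakpoints_per_chrom)
    return bkps


def _state_of(mean: float, cfg: SegmentationConfig) -> int:
    if mean > cfg.gain_threshold:
        return GAIN
    if mean < cfg.loss_threshold:
        return LOSS
    return NEUTRAL


def segment_profile(profile: SampleProfile, cfg: SegmentationConfig | None = None) -> SegmentedProfile:
    """Piecewise-constant segmentation of a combined-ratio profile.

    Each chromosome is fit independently by exact dynamic programming that
    minimizes total within-segment squared error plus ``penalty_lambda`` per
    breakpoint (breakpoint count capped). Missing clones carry no value but
    belong to the covering segment; clones between two fitted segments attach
    to the left segment. Chromosomes with no usable clone are skipped.
    """
    cfg = cfg or SegmentationConfig()
    result = SegmentedProfile(sample_id=profile.sample_id)
    for chrom in dict.fromkeys(profile.chrom.tolist()):  # preserve order
        cidx = np.flatnonzero(profile.chrom == chrom)
        lo, hi = int(cidx[0]), int(cidx[-1]) + 1
        ok = cidx[~profile.missing[cidx]]
        if ok.size == 0:
            continue
        values = profile.log2[ok]
        bkps = segment_values(values, cfg)
        bounds = [0] + bkps + [len(values)]
        prev_end = lo
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            seg_vals = values[b0:b1]
            mean = float(seg_vals.mean())
            start_idx = prev_end
            # boundary in full-index space: just before the first non-missing
            # clone of the next segment (missing run joins the left segment)
            end_idx = int(ok[b1]) if b1 < len(values) else hi
            result.segments.append(
                Segment(chrom=chrom, start_idx=start_idx, end_idx=end_idx,
                        mean_log2=mean, state=_state_of(mean, cfg))
            )
            prev_end = end_idx
    return result


def call_states(seg: SegmentedProfile, profile: SampleProfile) -> np.ndarray:
    """Per-clone copy-number state vector in {-1, 0, +1}; NaN where missing."""
    return seg.states_per_clone(profile.n_clones, profile.missing)


def detect_amplifications(
    profile: SampleProfile,
    cfg: AmplificationConfig | None = None,
    values: np.ndarray | None = None,
) -> list[Amplicon]:
    """Maximal runs of consecutive clones above the amplification threshold.

    Runs cannot bridge missing clones or chromosome boundaries and must span
    at least ``min_consecutive_elements`` clones. ``values`` defaults to the
    combined log2 ratios; pass segment means to run on smoothed values.
    """
    cfg = cfg or AmplificationConfig()
    if values is None:
        values = profile.log2
    ok = (~profile.missing) & ~np.isnan(values) & (values > cfg.log2_threshold)
    out: list[Amplicon] = []
    n = profile.n_clones
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and profile.chrom[j + 1] == profile.chrom[i]:
            j += 1
        if j - i + 1 >= cfg.min_consecutive_elements:
            out.append(Amplicon(
                chrom=str(profile.chrom[i]),
                start_idx=i, end_idx=j + 1,
                start_bp=int(profile.start[i]), end_bp=int(profile.end[j]),
                mean_log2=float(np.nanmean(values[i:j + 1])),
            ))
        i = j + 1
    return out


def amplification_score(
    samples: list[SampleProfile],
    cfg: AmplificationConfig | None = None,
    values_per_sample: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-clone count and fraction of samples whose amplicons cover the clone.

    All profiles must share one clone grid (same ids and positions).
    """
    if not samples:
        raise ValueError("at least one sample required")
    ref = samples[0]
    for s in samples[1:]:
        if not (np.array_equal(s.clone_ids, ref.clone_ids)
                and np.array_equal(s.start, ref.start)):
            raise ValueError("clone grids differ between samples")
    counts = np.zeros(ref.n_clones, dtype=int)
    for k, s in enumerate(samples):
        vals = values_per_sample[k] if values_per_sample is not None else None
        for amp in detect_amplifications(s, cfg, values=vals):
            counts[amp.start_idx:amp.end_idx] += 1
    return counts, counts / len(samples)
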