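"""Synthetic aCGH + expression cohorts with planted ground truth.

Generates tiling-path copy-number profiles for two tumor cohorts with
differential regional gain/loss frequencies, a high-noise preinvasive
(CIS-like) cohort, and expression for tumor cohorts plus an expression-only
normal cohort. A planted driver gene has dosage-coupled, tumor-elevated
expression; a panel of decoy genes each violates exactly one criterion of the
candidate-driver cascade. True segment states are piecewise constant, matching
the segmentation model assumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import SampleProfile
from .integration import ExpressionMatrix

# cascade criterion names used for decoy ground truth
CRIT_REGION = "disparity_region"
CRIT_DE = "differential_expression"
CRIT_RHO = "dosage_correlation"
CRIT_GROUP = "dosage_group"
CRIT_TVN = "tumor_vs_normal"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRegion:
    """A copy-number alteration planted in one cohort.

    ``mean_log2_shift`` is the magnitude of the carrier shift; its sign comes
    from ``state``. ``amp_carrier_fraction``/``amp_log2_shift`` override the
    simulation-wide values for this region (gain regions only).
    """

    start_bp: int
    end_bp: int
    cohort: str
    state: int                    # +1 gain, -1 loss
    carrier_fraction: float
    mean_log2_shift: float
    tag: str = ""
    amp_carrier_fraction: float | None = None
    amp_log2_shift: float | None = None

    def __post_init__(self):
        if self.state not in (-1, 1):
            raise ConfigurationError("state must be -1 or +1")
        if not (0 <= self.carrier_fraction <= 1):
            raise ConfigurationError("carrier_fraction must lie in [0, 1]")
        if self.start_bp >= self.end_bp or self.start_bp < 0:
            raise ConfigurationError("need 0 <= start_bp < end_bp")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Expression layer settings (log10 ratio scale).

    ``tumor_elevation`` is the lineage-specific expression shift of coupled
    genes in the gained cohort; ``dosage_slope`` couples expression to the true
    mean log2 dosage over the gene interval. The mean-guard decoy's silenced
    carriers sit ``silenced_offset`` below baseline; the normal-elevated decoy
    targets a tumor/normal fold of ``decoy_normal_fold``.
    """

    n_genes: int = 40
    genes_in_region: int = 8
    dosage_slope: float = 1.0
    expr_noise_sd: float = 0.05
    normal_baseline_shift: float = 0.0
    tumor_elevation: float = 0.6
    decoy_normal_fold: float = 1.3
    silenced_offset: float = -16.0
    n_silenced_carriers: int = 1


def _default_regions() -> list[PlantedRegion]:
    return [
        # telomeric loss, frequent in both cohorts: the frequency difference
        # (9 percentage points) deliberately fails the >10% filter
        PlantedRegion(0, 6_000_000, "AC", -1, 0.39, 0.5, tag="telomeric_loss"),
        PlantedRegion(0, 6_000_000, "SqCC", -1, 0.30, 0.5, tag="telomeric_loss"),
        # the lineage-specific driver amplicon
        PlantedRegion(9_000_000, 11_500_000, "SqCC", 1, 0.40, 0.45, tag="driver_gain"),
        PlantedRegion(9_000_000, 11_500_000, "AC", 1, 0.05, 0.45, tag="driver_gain"),
        # a gain shared equally by both cohorts: altered but not a disparity
        PlantedRegion(17_000_000, 19_000_000, "SqCC", 1, 0.40, 0.45, tag="shared_gain"),
        PlantedRegion(17_000_000, 19_000_000, "AC", 1, 0.40, 0.45, tag="shared_gain"),
        # early-event amplification in the preinvasive cohort over the driver locus
        PlantedRegion(9_600_000, 10_400_000, "CIS", 1, 0.50, 0.55, tag="cis_amp",
                      amp_carrier_fraction=0.70, amp_log2_shift=1.2),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"AC": 50, "SqCC": 50, "normal": 30, "CIS": 20})
    n_clones: int = 300
    clone_spacing_bp: int = 80_000
    chrom_length_bp: int = 24_000_000
    chrom_name: str = "8p-sim"
    planted_regions: list[PlantedRegion] = field(default_factory=_default_regions)
    amp_carrier_fraction: float = 0.30
    amp_log2_shift: float = 1.0
    probe_noise_sd: float = 0.04
    n_replicate_spots: int = 3
    qc_fail_fraction: float = 0.02
    shift_attenuation: tuple[float, float] = (0.75, 1.25)
    # random passenger alterations per genome, placed outside planted regions;
    # they give every profile realistic structure so per-sample Z-scores are
    # well defined even for samples with no planted alteration
    n_background_segments: int = 3
    background_shift: float = 0.3
    background_len_bp: int = 1_600_000
    # expression is generated for a subset of each tumor cohort (None = all),
    # with the gained cohort's subset stratified to a fixed number of
    # driver-region carriers, mirroring a matched CGH+expression panel
    expr_samples_per_cohort: dict[str, int] | None = field(
        default_factory=lambda: {"AC": 34, "SqCC": 13})
    expr_stratify_carriers: int | None = 6
    tumor_cohorts: tuple[str, str] = ("AC", "SqCC")
    expression_only_cohorts: tuple[str, ...] = ("normal",)
    cis_cohort: str = "CIS"
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_clones <= 0 or self.clone_spacing_bp <= 0:
            raise ConfigurationError("n_clones and clone_spacing_bp must be positive")
        if self.n_clones * self.clone_spacing_bp > self.chrom_length_bp:
            raise ConfigurationError("clone grid exceeds chromosome length")
        if not (0 <= self.amp_carrier_fraction <= 1):
            raise ConfigurationError("amp_carrier_fraction must lie in [0, 1]")
        if self.n_replicate_spots < 2:
            raise ConfigurationError("need at least 2 replicate spots")
        by_cohort: dict[str, list[PlantedRegion]] = {}
        for r in self.planted_regions:
            if r.end_bp > self.chrom_length_bp:
                raise ConfigurationError("planted region outside chromosome")
            by_cohort.setdefault(r.cohort, []).append(r)
        for cohort, regs in by_cohort.items():
            regs = sorted(regs, key=lambda r: r.start_bp)
            for a, b in zip(regs[:-1], regs[1:]):
                if b.start_bp < a.end_bp:
                    raise ConfigurationError(
                        f"overlapping planted regions in cohort {cohort!r}")


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    clone_start: np.ndarray
    clone_end: np.ndarray
    # per profiled cohort: (n_clones, n_samples) arrays
    true_states: dict[str, np.ndarray]
    true_shifts: dict[str, np.ndarray]
    # carriers[(cohort, tag)] -> sample indices; amp_carriers likewise
    carriers: dict[tuple[str, str], np.ndarray]
    amp_carriers: dict[tuple[str, str], np.ndarray]
    differential_regions: list[dict]
    genes: pd.DataFrame          # gene, chrom, start, end, role, expected_failure
    driver_genes: list[str]
    decoy_failures: dict[str, str]

    def gene_interval(self, gene: str) -> tuple[int, int]:
        row = self.genes.set_index("gene").loc[gene]
        return int(row["start"]), int(row["end"])


def _quiet_zones(cfg: SimulationConfig, margin: int = 200_000,
                 min_len: int | None = None) -> list[tuple[int, int]]:
    """Intervals free of planted regions (any cohort), with a safety margin."""
    if min_len is None:
        min_len = cfg.background_len_bp
    occupied = sorted({(r.start_bp, r.end_bp) for r in cfg.planted_regions})
    merged: list[list[int]] = []
    for lo, hi in occupied:
        lo, hi = max(0, lo - margin), min(cfg.chrom_length_bp, hi + margin)
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    zones, prev = [], 0
    for lo, hi in merged:
        if lo - prev >= min_len:
            zones.append((prev, lo))
        prev = hi
    if cfg.chrom_length_bp - prev >= min_len:
        zones.append((prev, cfg.chrom_length_bp))
    return zones


def _clone_membership(cfg: SimulationConfig, region: PlantedRegion) -> np.ndarray:
    centers = (np.arange(cfg.n_clones) + 0.5) * cfg.clone_spacing_bp
    return (centers >= region.start_bp) & (centers < region.end_bp)


def _planted_differential(cfg: SimulationConfig) -> list[dict]:
    """Regions expected to survive the disparity filters, from carrier fractions."""
    a, b = cfg.tumor_cohorts
    spans: dict[tuple[int, int, int], dict[str, float]] = {}
    for r in cfg.planted_regions:
        if r.cohort in (a, b):
            spans.setdefault((r.start_bp, r.end_bp, r.state), {})[r.cohort] = r.carrier_fraction
    out = []
    for (start, end, state), fr in spans.items():
        fa, fb = fr.get(a, 0.0), fr.get(b, 0.0)
        if abs(fa - fb) > 0.10 and max(fa, fb) > 0.20:
            out.append({"start_bp": start, "end_bp": end, "state": state,
                        "cohort_high": b if fb > fa else a,
                        "freq_a": fa, "freq_b": fb})
    return out


def _build_gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    ex = cfg.expression
    drivers = [r for r in cfg.planted_regions
               if r.tag == "driver_gain" and r.cohort == cfg.tumor_cohorts[1]]
    shared = [r for r in cfg.planted_regions
              if r.tag == "shared_gain" and r.cohort == cfg.tumor_cohorts[1]]
    rows = []

    def add(name, start, role, failure=None, length=100_000):
        rows.append({"gene": name, "chrom": cfg.chrom_name, "start": int(start),
                     "end": int(start + length), "role": role,
                     "expected_failure": failure})

    if drivers:
        lo, hi = drivers[0].start_bp, drivers[0].end_bp
        span = hi - lo
        add("GENE_DRIVER", lo + int(0.32 * span), "driver")
        add("DEC_NODE", lo + int(0.08 * span), "decoy", CRIT_DE)
        add("DEC_NORMHI", lo + int(0.20 * span), "decoy", CRIT_TVN)
        add("DEC_RANK", lo + int(0.56 * span), "decoy", CRIT_RHO)
        add("DEC_GUARD", lo + int(0.72 * span), "decoy", CRIT_GROUP)
        n_pass = max(0, ex.genes_in_region - 5)
        for i in range(n_pass):
            add(f"PASS_R{i+1}",
                lo + int((0.40 + 0.44 * (i + 1) / (n_pass + 1)) * span),
                "passenger", CRIT_DE)
    if shared:
        add("DEC_OFFREG",
            shared[0].start_bp + (shared[0].end_bp - shared[0].start_bp) // 2,
            "decoy", CRIT_REGION)
    # background genes spread over copy-number-quiet zones
    n_bg = max(0, cfg.expression.n_genes - len(rows))
    quiet = _quiet_zones(cfg, min_len=400_000) or [(0, cfg.chrom_length_bp)]
    total = sum(b - a for a, b in quiet)
    k = 0
    for zi, (zlo, zhi) in enumerate(quiet):
        n_zone = (int(round(n_bg * (zhi - zlo) / total))
                  if zi < len(quiet) - 1 else n_bg - k)
        for i in range(n_zone):
            if k >= n_bg:
                break
            add(f"BG{k+1:02d}",
                zlo + 100_000 + int((zhi - zlo - 300_000) * i / max(n_zone, 1)),
                "background")
            k += 1
    return pd.DataFrame(rows)


def simulate_cohorts(cfg: SimulationConfig) -> tuple[dict[str, list[SampleProfile]], GroundTruth]:
    """Simulate per-sample probe profiles and the planted ground truth.

    Each clone carries ``n_replicate_spots`` replicate log2 draws around the
    sample's true segment level; a ``qc_fail_fraction`` of clones per sample is
    injected with inflated replicate noise or sub-threshold signal-to-noise to
    exercise quality control. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_clones
    start = np.arange(n) * cfg.clone_spacing_bp
    end = start + cfg.clone_spacing_bp
    clone_ids = np.array([f"CLN{i:04d}" for i in range(n)])
    chrom = np.full(n, cfg.chrom_name)

    profiled = [c for c in cfg.n_samples_per_cohort
                if c not in cfg.expression_only_cohorts]
    true_states: dict[str, np.ndarray] = {}
    true_shifts: dict[str, np.ndarray] = {}
    carriers: dict[tuple[str, str], np.ndarray] = {}
    amp_carriers: dict[tuple[str, str], np.ndarray] = {}

    for cohort in profiled:
        ns = cfg.n_samples_per_cohort[cohort]
        states = np.zeros((n, ns), dtype=int)
        shifts = np.zeros((n, ns))
        for r in cfg.planted_regions:
            if r.cohort != cohort:
                continue
            member = _clone_membership(cfg, r)
            n_car = int(round(r.carrier_fraction * ns))
            order = rng.permutation(ns)
            car = np.sort(order[:n_car])
            carriers[(cohort, r.tag or f"{r.start_bp}-{r.end_bp}")] = car
            amp_frac = (r.amp_carrier_fraction if r.amp_carrier_fraction is not None
                        else cfg.amp_carrier_fraction)
            amp_set = np.array([], dtype=int)
            if r.state > 0 and amp_frac > 0 and n_car > 0:
                n_amp = int(round(amp_frac * n_car))
                amp_set = np.sort(order[:n_car][:n_amp])
            amp_carriers[(cohort, r.tag or f"{r.start_bp}-{r.end_bp}")] = amp_set
            amp_shift = (r.amp_log2_shift if r.amp_log2_shift is not None
                         else cfg.amp_log2_shift)
            for s in car:
                base = amp_shift if s in amp_set else r.mean_log2_shift
                mult = rng.uniform(*cfg.shift_attenuation)
                shifts[member, s] += r.state * base * mult
                states[member, s] = r.state
        # random passenger segments outside the planted regions
        zones = _quiet_zones(cfg)
        if zones and cfg.n_background_segments > 0:
            zlens = np.array([hi - lo for lo, hi in zones], dtype=float)
            centers = (start + end) / 2.0
            for s in range(ns):
                for _ in range(cfg.n_background_segments):
                    zi = rng.choice(len(zones), p=zlens / zlens.sum())
                    zlo, zhi = zones[zi]
                    seg_len = min(cfg.background_len_bp, zhi - zlo)
                    pos = zlo if zhi - zlo == seg_len else int(rng.integers(zlo, zhi - seg_len))
                    sign = 1 if rng.random() < 0.5 else -1
                    member = (centers >= pos) & (centers < pos + seg_len)
                    shifts[member, s] += sign * cfg.background_shift
            states = np.where(shifts > 1e-12, 1, np.where(shifts < -1e-12, -1, 0))
        true_states[cohort] = states
        true_shifts[cohort] = shifts

    profiles: dict[str, list[SampleProfile]] = {}
    for cohort in profiled:
        ns = cfg.n_samples_per_cohort[cohort]
        profiles[cohort] = []
        for s in range(ns):
            mu = true_shifts[cohort][:, s]
            noise_sd = np.full(n, cfg.probe_noise_sd)
            snr = rng.uniform(10, 40, size=n)
            n_fail = int(round(cfg.qc_fail_fraction * n))
            if n_fail:
                fail_idx = rng.choice(n, size=n_fail, replace=False)
                half = n_fail // 2
                noise_sd[fail_idx[:half]] = 4 * cfg.probe_noise_sd  # inflated SD
                snr[fail_idx[half:]] = rng.uniform(1.0, 2.9, size=n_fail - half)
            reps = mu[:, None] + rng.normal(0, 1, size=(n, cfg.n_replicate_spots)) * noise_sd[:, None]
            rep_sd = reps.std(axis=1, ddof=1)
            profiles[cohort].append(SampleProfile(
                sample_id=f"{cohort}{s:03d}",
                clone_ids=clone_ids, chrom=chrom, start=start, end=end,
                log2=reps.mean(axis=1), missing=np.zeros(n, dtype=bool),
                replicates=reps, replicate_sd=rep_sd, snr=snr,
            ))

    truth = GroundTruth(
        clone_start=start, clone_end=end,
        true_states=true_states, true_shifts=true_shifts,
        carriers=carriers, amp_carriers=amp_carriers,
        differential_regions=_planted_differential(cfg),
        genes=_build_gene_table(cfg),
        driver_genes=["GENE_DRIVER"],
        decoy_failures={
            row["gene"]: row["expected_failure"]
            for _, row in _build_gene_table(cfg).iterrows()
            if row["role"] == "decoy"
        },
    )
    return profiles, truth


def _gene_dosage(cfg: SimulationConfig, truth: GroundTruth, cohort: str,
                 start: int, end: int) -> np.ndarray:
    """True mean log2 shift over a gene interval, per sample of a cohort."""
    if cohort not in truth.true_shifts:
        ns = cfg.n_samples_per_cohort[cohort]
        return np.zeros(ns)
    overlap = np.minimum(truth.clone_end, end) - np.maximum(truth.clone_start, start)
    w = np.clip(overlap, 0, None).astype(float)
    if w.sum() == 0:
        return np.zeros(truth.true_shifts[cohort].shape[1])
    return (truth.true_shifts[cohort] * w[:, None]).sum(axis=0) / w.sum()


def simulate_expression(cfg: SimulationConfig, truth: GroundTruth,
                        profiles: dict[str, list[SampleProfile]]) -> ExpressionMatrix:
    """Simulate probe-level expression (log10 ratio scale) for tumor + normal cohorts.

    Driver-gene expression is lineage-elevated and dosage-coupled; each decoy
    breaks exactly one cascade criterion; background genes are pure noise. The
    ``profiles`` argument fixes the sample set (truth/profile mismatch raises).
    """
    ex = cfg.expression
    a_coh, b_coh = cfg.tumor_cohorts
    for cohort in (a_coh, b_coh):
        if cohort not in profiles:
            raise ValueError(f"profiles for cohort {cohort!r} required")
        if len(profiles[cohort]) != cfg.n_samples_per_cohort[cohort]:
            raise ValueError(f"profile count mismatch for cohort {cohort!r}")
    normal = cfg.expression_only_cohorts[0] if cfg.expression_only_cohorts else None
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    # expression subset per tumor cohort; the gained cohort's subset is
    # stratified to a fixed number of driver-region carriers
    subset: dict[str, np.ndarray] = {}
    for c in (a_coh, b_coh):
        ncoh = cfg.n_samples_per_cohort[c]
        want = (None if cfg.expr_samples_per_cohort is None
                else cfg.expr_samples_per_cohort.get(c))
        if want is None or want >= ncoh:
            subset[c] = np.arange(ncoh)
            continue
        car = truth.carriers.get((c, "driver_gain"), np.array([], dtype=int))
        if c == b_coh and cfg.expr_stratify_carriers is not None and car.size:
            n_car = min(cfg.expr_stratify_carriers, car.size, want)
            non = np.setdiff1d(np.arange(ncoh), car)
            pick = [rng.choice(car, size=n_car, replace=False)] if n_car else []
            pick.append(rng.choice(non, size=min(want - n_car, non.size), replace=False))
            subset[c] = np.sort(np.concatenate(pick).astype(int))
        else:
            subset[c] = np.sort(rng.choice(ncoh, size=want, replace=False))

    cohorts_out = [a_coh, b_coh] + ([normal] if normal else [])
    sample_ids, labels = [], []
    for c in cohorts_out:
        if c in profiles:
            ids = [profiles[c][i].sample_id for i in subset[c]]
        else:
            ids = [f"{c}{i:03d}" for i in range(cfg.n_samples_per_cohort[c])]
        sample_ids += ids
        labels += [c] * len(ids)
    n_a = len(subset[a_coh])
    n_b = len(subset[b_coh])
    n_n = cfg.n_samples_per_cohort[normal] if normal else 0

    values: dict[str, np.ndarray] = {}
    probe_rows = []
    genes = truth.genes
    elev = ex.tumor_elevation
    for _, g in genes.iterrows():
        name, role = g["gene"], g["role"]
        b0 = rng.normal(0, 0.1)
        d_b = _gene_dosage(cfg, truth, b_coh, g["start"], g["end"])[subset[b_coh]]
        va = np.full(n_a, b0)
        vb = np.full(n_b, b0)
        vn = np.full(n_n, b0 + ex.normal_baseline_shift)
        if role == "driver":
            vb = b0 + elev + ex.dosage_slope * d_b
        elif g["expected_failure"] == CRIT_DE:        # not-DE decoy / passengers
            vb = b0 + elev + ex.dosage_slope * d_b
            matched = np.sort(d_b)[np.arange(n_a) % n_b]   # distribution-matched AC
            va = b0 + elev + ex.dosage_slope * matched
        elif g["expected_failure"] == CRIT_TVN:       # elevated in normals too
            vb = b0 + elev + ex.dosage_slope * d_b
            vn = np.full(n_n, b0 + ex.normal_baseline_shift + elev
                         - np.log10(ex.decoy_normal_fold))
        elif g["expected_failure"] == CRIT_RHO:
            # most carriers elevated above the neutral block but reverse-coupled
            # within carriers; the top-dosage quarter sits just below the block:
            # the gain group still wins the rank test while the sample-wise
            # rank correlation with dosage collapses
            vb = np.full(n_b, b0 + elev)
            car = np.flatnonzero(d_b > 0)
            neu = np.flatnonzero(d_b <= 0)
            if car.size:
                by_d = car[np.argsort(d_b[car], kind="stable")]
                n_low = car.size // 4
                high = by_d[:car.size - n_low] if n_low else by_d
                frac = np.linspace(0, 1, max(high.size, 2))[:high.size]
                vb[high] = b0 + elev + 0.45 - 0.20 * frac   # reversed in dosage
                if n_low:
                    low = by_d[car.size - n_low:]
                    vb[low] = b0 + elev - 0.15 + 0.10 * np.linspace(0, 1, max(n_low, 2))[:n_low]
            vb[neu] = b0 + elev + 0.20 * rng.random(neu.size)
        elif g["expected_failure"] == CRIT_GROUP:     # silenced carriers break the mean guard
            vb = b0 + elev + ex.dosage_slope * d_b
            car = np.flatnonzero(d_b > 0)
            if car.size:
                k = min(ex.n_silenced_carriers, car.size)
                lowest = car[np.argsort(d_b[car], kind="stable")[:k]]
                vb[lowest] = b0 + ex.silenced_offset
        elif g["expected_failure"] == CRIT_REGION:    # coupled, but its locus is not
            vb = b0 + elev + ex.dosage_slope * d_b    # a disparity region
        # background and AC defaults: baseline
        noise = lambda m: rng.normal(0, ex.expr_noise_sd, size=m) if ex.expr_noise_sd > 0 else 0.0
        va = va + noise(n_a)
        vb = vb + noise(n_b)
        vn = vn + noise(n_n)
        full = np.concatenate([va, vb, vn])
        probe1 = f"P_{name}_1"
        values[probe1] = full
        probe_rows.append({"probe_id": probe1, "gene": name, "chrom": g["chrom"],
                           "start": g["start"], "end": g["end"]})
        if role in ("driver",) or g["expected_failure"] == CRIT_TVN:
            # a second, dimmer probe exercises the probe-collapse rules
            probe2 = f"P_{name}_2"
            values[probe2] = full - 0.05 + noise(len(full))
            probe_rows.append({"probe_id": probe2, "gene": name, "chrom": g["chrom"],
                               "start": g["start"], "end": g["end"]})

    df = pd.DataFrame(values, index=sample_ids).T
    return ExpressionMatrix(
        values=df,
        probe_map=pd.DataFrame(probe_rows),
        cohorts=pd.Series(labels, index=sample_ids),
        scale="log10",
    )
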