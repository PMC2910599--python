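"""End-to-end orchestration of the integrative analysis on a simulated cohort.

Runs QC, segmentation and state calling per sample, the two-cohort disparity
comparison, high-level amplification scoring (tumor and preinvasive
thresholds), the dosage-expression integration on the gained cohort, the
candidate cascade, and the extreme-expresser signature analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acgh, compare, integration, synthetic
from .cascade import CandidateReport, run_cascade
from .signature import SamConfig, sam_two_class, select_extremes


@dataclass
class PipelineResult:
    config: synthetic.SimulationConfig
    truth: synthetic.GroundTruth
    profiles: dict[str, list[acgh.SampleProfile]]
    qc_reports: dict[str, list[acgh.QCReport]]
    segmented: dict[str, list[acgh.SegmentedProfile]]
    state_matrix: compare.StateMatrix
    regions: list[compare.DisparityRegion]
    amp_fraction_tumor: np.ndarray         # gained-cohort, threshold 0.6
    amp_fraction_cis: np.ndarray | None    # CIS cohort, threshold 0.8
    expression: integration.ExpressionMatrix
    de_genes: pd.DataFrame
    dosage_genes: pd.DataFrame
    tvn_genes: pd.DataFrame
    report: CandidateReport
    sam_table: pd.DataFrame | None = None
    sam_groups: tuple[list[str], list[str]] | None = None
    filter_log: dict[str, int] = field(default_factory=dict)


def build_state_matrix(profiles, segmented, cohorts_of) -> compare.StateMatrix:
    """Stack per-sample called states into a clones x samples StateMatrix."""
    all_samples, all_states, labels = [], [], []
    ref = None
    for cohort, plist in profiles.items():
        for prof, seg in zip(plist, segmented[cohort]):
            ref = ref or prof
            all_samples.append(prof.sample_id)
            labels.append(cohorts_of.get(prof.sample_id, cohort))
            all_states.append(acgh.call_states(seg, prof))
    return compare.StateMatrix(
        states=np.column_stack(all_states),
        clone_ids=ref.clone_ids, chrom=ref.chrom, start=ref.start, end=ref.end,
        sample_ids=np.array(all_samples), cohorts=np.array(labels),
    )


def process_cohort(profiles, qc_cfg=None, seg_cfg=None):
    """QC + segmentation for a list of profiles; returns (clean, reports, segmented)."""
    qc_cfg = qc_cfg or acgh.QCConfig()
    seg_cfg = seg_cfg or acgh.SegmentationConfig()
    clean, reports, segs = [], [], []
    for p in profiles:
        cp, rep = acgh.qc_filter(p, qc_cfg)
        clean.append(cp)
        reports.append(rep)
        segs.append(acgh.segment_profile(cp, seg_cfg))
    return clean, reports, segs


def integrate_genes(
    profiles_b: list[acgh.SampleProfile],
    segmented_b: list[acgh.SegmentedProfile],
    expr: integration.ExpressionMatrix,
    genes: pd.DataFrame,
    cohort_a: str, cohort_b: str, normal_cohort: str | None,
    icfg: integration.IntegrationConfig,
    chrom_length: int,
):
    """Differential expression, both dosage associations, tumor-vs-normal."""
    # per-probe DE, collapsed to genes by the lowest-p rule
    de_probes = integration.diff_expression(expr, cohort_a, cohort_b, "B>A")
    de_genes = integration.collapse_probes(de_probes, expr.probe_map, "min_p")

    # integration runs on the matched CGH + expression panel
    with_expr = set(expr.samples_in(cohort_b))
    pairs = [(p, s) for p, s in zip(profiles_b, segmented_b)
             if p.sample_id in with_expr]
    profiles_b = [p for p, _ in pairs]
    segmented_b = [s for _, s in pairs]
    samples_b = [p.sample_id for p in profiles_b]
    zs = {}
    for p in profiles_b:
        _, z = integration.windowed_zscore(p, icfg.window_bp, chrom_length)
        zs[p.sample_id] = z
    window_starts = np.arange(len(next(iter(zs.values())))) * icfg.window_bp

    probe_of_gene = (expr.probe_map.groupby("gene")["probe_id"].first())
    rows = {}
    for _, g in genes.iterrows():
        gene = g["gene"]
        start, end = int(g["start"]), int(g["end"])
        dz = np.array([integration.gene_zscore(window_starts, zs[s], icfg.window_bp,
                                               start, end) for s in samples_b])
        status = np.array([integration.gene_status(seg, prof, start, end)
                           for seg, prof in zip(segmented_b, profiles_b)])
        # gene expression: collapse by the DE-chosen probe where available
        probe = de_genes["probe_id"].get(gene, probe_of_gene.get(gene))
        ev = expr.values.loc[probe, samples_b].to_numpy(dtype=float)
        # samples whose clones at the locus were all QC-removed have no
        # windowed dosage; drop those pairs
        valid = np.isfinite(dz) & np.isfinite(ev)
        if valid.sum() >= 4:
            rho, p = integration.dosage_correlation(dz[valid], ev[valid])
        else:
            rho, p = float("nan"), float("nan")
        gt = integration.dosage_group_test(ev, status)
        rows[gene] = {"rho": rho, "p": p, "group_p": gt.p,
                      "median_higher": gt.median_higher, "mean_higher": gt.mean_higher,
                      "group_testable": gt.testable, "n_gain": gt.n_gain,
                      "n_neutral": gt.n_neutral, "n_loss_excluded": gt.n_loss_excluded}
    dosage = pd.DataFrame.from_dict(rows, orient="index")
    from .stats import bh_adjust
    dosage["p_adj"] = bh_adjust(dosage["p"].to_numpy())
    dosage["group_p_adj"] = bh_adjust(dosage["group_p"].to_numpy())

    tvn_rows = {}
    if normal_cohort is not None:
        sn = expr.samples_in(normal_cohort)
        for _, g in genes.iterrows():
            gene = g["gene"]
            probe = de_genes["probe_id"].get(gene, probe_of_gene.get(gene))
            tv = expr.values.loc[probe, samples_b].to_numpy(dtype=float)
            nv = expr.values.loc[probe, sn].to_numpy(dtype=float)
            fold, p = integration.tumor_vs_normal(expr, tv, nv)
            tvn_rows[gene] = {"fold": fold, "p": p}
    tvn = pd.DataFrame.from_dict(tvn_rows, orient="index")
    if len(tvn):
        tvn["p_adj"] = bh_adjust(tvn["p"].to_numpy())
    return de_genes, dosage, tvn


def run_pipeline(
    cfg: synthetic.SimulationConfig,
    qc_cfg: acgh.QCConfig | None = None,
    seg_cfg: acgh.SegmentationConfig | None = None,
    cmp_cfg: compare.ComparisonConfig | None = None,
    icfg: integration.IntegrationConfig | None = None,
    sam_cfg: SamConfig | None = None,
    run_sam: bool = True,
) -> PipelineResult:
    """Simulate a dataset and run every analysis stage on it."""
    qc_cfg = qc_cfg or acgh.QCConfig()
    seg_cfg = seg_cfg or acgh.SegmentationConfig()
    cmp_cfg = cmp_cfg or compare.ComparisonConfig()
    icfg = icfg or integration.IntegrationConfig()
    cohort_a, cohort_b = cfg.tumor_cohorts

    raw_profiles, truth = synthetic.simulate_cohorts(cfg)
    expr = synthetic.simulate_expression(cfg, truth, raw_profiles)

    profiles, qc_reports, segmented = {}, {}, {}
    for cohort, plist in raw_profiles.items():
        clean, reports, segs = process_cohort(plist, qc_cfg, seg_cfg)
        profiles[cohort] = clean
        qc_reports[cohort] = reports
        segmented[cohort] = segs

    tumor_profiles = {c: profiles[c] for c in (cohort_a, cohort_b)}
    tumor_segs = {c: segmented[c] for c in (cohort_a, cohort_b)}
    sm = build_state_matrix(tumor_profiles, tumor_segs, {})
    regions = compare.compare_cohorts(sm, cohort_a, cohort_b, cmp_cfg)

    amp_tumor_cfg = acgh.AmplificationConfig(log2_threshold=0.6)
    _, amp_frac_tumor = acgh.amplification_score(profiles[cohort_b], amp_tumor_cfg)
    amp_frac_cis = None
    if cfg.cis_cohort in profiles:
        amp_cis_cfg = acgh.AmplificationConfig(log2_threshold=0.8)
        _, amp_frac_cis = acgh.amplification_score(profiles[cfg.cis_cohort], amp_cis_cfg)

    normal = cfg.expression_only_cohorts[0] if cfg.expression_only_cohorts else None
    de_genes, dosage, tvn = integrate_genes(
        profiles[cohort_b], segmented[cohort_b], expr, truth.genes,
        cohort_a, cohort_b, normal, icfg, cfg.chrom_length_bp)

    report = run_cascade(truth.genes, regions, de_genes, dosage, tvn, icfg)

    sam_table, sam_groups = None, None
    if run_sam and truth.driver_genes:
        sam_cfg = sam_cfg or SamConfig(seed=cfg.seed)
        tumor_samples = [s for s in expr.values.columns
                         if expr.cohorts[s] in (cohort_a, cohort_b)]
        tumor_expr = integration.ExpressionMatrix(
            values=expr.values[tumor_samples], probe_map=expr.probe_map,
            cohorts=expr.cohorts[tumor_samples], scale=expr.scale)
        high, low = select_extremes(tumor_expr, truth.driver_genes[0], sam_cfg)
        sam_table = sam_two_class(tumor_expr, high, low, sam_cfg)
        sam_groups = (high, low)

    filter_log = {
        "clones": cfg.n_clones,
        "qc_removed_total": int(sum(r.n_removed for rs in qc_reports.values() for r in rs)),
        "regions_reported": len(regions),
        "genes_tested": int(len(truth.genes)),
        "genes_de_significant": int((de_genes["p_adj"] <= icfg.alpha_de).sum()),
        "genes_candidates": len(report.candidates),
    }
    return PipelineResult(
        config=cfg, truth=truth, profiles=profiles, qc_reports=qc_reports,
        segmented=segmented, state_matrix=sm, regions=regions,
        amp_fraction_tumor=amp_frac_tumor, amp_fraction_cis=amp_frac_cis,
        expression=expr, de_genes=de_genes, dosage_genes=dosage, tvn_genes=tvn,
        report=report, sam_table=sam_table, sam_groups=sam_groups,
        filter_log=filter_log,
    )
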