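"""Candidate-driver filtering cascade.

Combines disparity-region membership, cohort differential expression, both
dosage-association methods and tumor-versus-normal elevation into a ranked
per-gene report. Genes failing exactly one criterion are listed as near-misses
with the failed criterion named; genes missing from any upstream result set
are reported as untestable, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import DisparityRegion
from .integration import IntegrationConfig

CRITERIA = (
    "disparity_region",
    "differential_expression",
    "dosage_correlation",
    "dosage_group",
    "tumor_vs_normal",
)


@dataclass
class CandidateReport:
    """Per-gene audit of every cascade criterion.

    ``table`` has one row per gene with every statistic, a pass flag per
    criterion, the final candidate flag, and for near-misses the single failed
    criterion. ``candidates`` are sorted by Spearman rho descending.
    """

    table: pd.DataFrame
    candidates: list[str] = field(default_factory=list)
    near_misses: dict[str, str] = field(default_factory=dict)
    untestable: list[str] = field(default_factory=list)


def _region_of(interval: tuple[int, int], chrom: str,
               regions: list[DisparityRegion]) -> int | None:
    start, end = interval
    for i, r in enumerate(regions):
        if r.chrom == chrom and r.end_bp > start and r.start_bp < end:
            return i
    return None


def run_cascade(
    gene_intervals: pd.DataFrame,          # gene, chrom, start, end
    regions: list[DisparityRegion],
    de_results: pd.DataFrame,              # index gene: p, p_adj
    dosage_results: pd.DataFrame,          # index gene: rho, p_adj, group_p_adj,
                                           #   median_higher, mean_higher, group_testable
    tvn_results: pd.DataFrame,             # index gene: fold, p, p_adj
    cfg: IntegrationConfig | None = None,
) -> CandidateReport:
    """Evaluate every gene against the five candidate-driver criteria.

    A candidate must lie in a disparity region, be differentially expressed
    between the cohorts (BH p <= alpha_de), show a dosage correlation with
    rho > rho_min at BH p <= alpha_rho, show elevated expression in
    gain/amplified versus neutral samples (BH p <= alpha_dosage with both
    median and mean guards), and be elevated >= fold_min over normals at
    BH p <= alpha_de.
    """
    cfg = cfg or IntegrationConfig()
    rows = []
    untestable = []
    for _, g in gene_intervals.iterrows():
        gene = g["gene"]
        missing_from = [name for name, df in
                        (("de", de_results), ("dosage", dosage_results), ("tvn", tvn_results))
                        if gene not in df.index]
        if missing_from:
            untestable.append(gene)
            rows.append({"gene": gene, "untestable": True,
                         "missing_from": ",".join(missing_from)})
            continue
        de = de_results.loc[gene]
        do = dosage_results.loc[gene]
        tv = tvn_results.loc[gene]
        region_id = _region_of((int(g["start"]), int(g["end"])), g["chrom"], regions)
        flags = {
            "disparity_region": region_id is not None,
            "differential_expression": bool(de["p_adj"] <= cfg.alpha_de),
            "dosage_correlation": bool(do["rho"] > cfg.rho_min
                                       and do["p_adj"] <= cfg.alpha_rho),
            "dosage_group": bool(do.get("group_testable", True)
                                 and do["group_p_adj"] <= cfg.alpha_dosage
                                 and do["median_higher"] and do["mean_higher"]),
            "tumor_vs_normal": bool(np.isfinite(tv["fold"]) and tv["fold"] >= cfg.fold_min
                                    and tv["p_adj"] <= cfg.alpha_de),
        }
        failed = [c for c in CRITERIA if not flags[c]]
        rows.append({
            "gene": gene, "untestable": False, "missing_from": "",
            "region_id": region_id if region_id is not None else -1,
            "de_p_adj": float(de["p_adj"]),
            "rho": float(do["rho"]), "rho_p_adj": float(do["p_adj"]),
            "group_p_adj": float(do["group_p_adj"]),
            "median_higher": bool(do["median_higher"]),
            "mean_higher": bool(do["mean_higher"]),
            "fold": float(tv["fold"]), "tvn_p": float(tv["p"]),
            "tvn_p_adj": float(tv["p_adj"]),
            **{f"pass_{c}": flags[c] for c in CRITERIA},
            "n_failed": len(failed),
            "failed_criteria": ";".join(failed),
            "candidate": not failed,
        })
    table = pd.DataFrame(rows).set_index("gene")
    tested = table[~table["untestable"]]
    candidates = (tested[tested["candidate"] == True]  # noqa: E712
                  .sort_values("rho", ascending=False).index.tolist())
    near = tested[tested["n_failed"] == 1]
    near_misses = {g: row["failed_criteria"] for g, row in near.iterrows()}
    return CandidateReport(table=table, candidates=candidates,
                           near_misses=near_misses, untestable=untestable)
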