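"""Readers and writers for the on-disk formats.

Probe tables, expression matrices and cohort labels are tab-delimited text;
segments are written as IGV SEG, regions and amplicons as BED (0-based
half-open), audit trails as JSON. All writes are atomic (temp file + rename)
and floats are fixed at six significant digits for stable outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acgh import Amplicon, SampleProfile, SegmentedProfile
from .compare import DisparityRegion

FLOAT_FMT = "%.6g"


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return FLOAT_FMT % x
    return str(x)


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class FormatError(ValueError):
    pass


def read_probe_table(path: str | Path, one_based: bool = False,
                     sample_id: str | None = None) -> SampleProfile:
    """Read a per-sample probe TSV into a SampleProfile.

    Expected header: ``clone_id chrom start end log2_rep1..k sd snr``.
    With ``one_based`` the input coordinates are 1-based inclusive and are
    converted to the internal 0-based half-open convention. Rows are sorted by
    (chrom, start); duplicate clone ids and malformed intervals are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"clone_id", "chrom", "start", "end", "sd", "snr"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    rep_cols = [c for c in df.columns if c.startswith("log2_rep")]
    if not rep_cols:
        raise FormatError(f"{path}: no log2_rep* replicate columns")
    if df["clone_id"].duplicated().any():
        dup = df.loc[df["clone_id"].duplicated(), "clone_id"].iloc[0]
        raise FormatError(f"{path}: duplicate clone id {dup!r}")
    start = df["start"].to_numpy(dtype=int)
    end = df["end"].to_numpy(dtype=int)
    if one_based:
        start = start - 1
    bad = np.flatnonzero(start >= end)
    if bad.size:
        raise FormatError(f"{path}: line {bad[0] + 2}: start >= end")
    order = np.lexsort((start, df["chrom"].to_numpy()))
    reps = df[rep_cols].to_numpy(dtype=float)[order]
    return SampleProfile(
        sample_id=sample_id or path.stem,
        clone_ids=df["clone_id"].to_numpy(dtype=object)[order],
        chrom=df["chrom"].to_numpy(dtype=object)[order],
        start=start[order], end=end[order],
        log2=reps.mean(axis=1),
        missing=np.zeros(len(df), dtype=bool),
        replicates=reps,
        replicate_sd=df["sd"].to_numpy(dtype=float)[order],
        snr=df["snr"].to_numpy(dtype=float)[order],
    )


def write_probe_table(profile: SampleProfile, path: str | Path) -> None:
    k = profile.replicates.shape[1] if profile.replicates is not None else 1
    header = ["clone_id", "chrom", "start", "end"] \
        + [f"log2_rep{i+1}" for i in range(k)] + ["sd", "snr"]
    lines = ["\t".join(header)]
    for i in range(profile.n_clones):
        reps = (profile.replicates[i] if profile.replicates is not None
                else [profile.log2[i]])
        row = [profile.clone_ids[i], profile.chrom[i],
               str(int(profile.start[i])), str(int(profile.end[i]))]
        row += [_fmt(v) for v in reps]
        row += [_fmt(profile.replicate_sd[i] if profile.replicate_sd is not None else 0.0),
                _fmt(profile.snr[i] if profile.snr is not None else 0.0)]
        lines.append("\t".join(row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_seg(segmented: SegmentedProfile, profile: SampleProfile,
              path: str | Path) -> None:
    """IGV SEG format: sample, chrom, start, end, num probes, segment mean."""
    lines = ["sample\tchrom\tstart\tend\tnum_probes\tseg_mean"]
    for seg in segmented.segments:
        lines.append("\t".join([
            segmented.sample_id, seg.chrom,
            str(int(profile.start[seg.start_idx])),
            str(int(profile.end[seg.end_idx - 1])),
            str(seg.end_idx - seg.start_idx),
            _fmt(seg.mean_log2),
        ]))
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_bed(intervals, path: str | Path, header_comment: str = "") -> None:
    """BED (0-based half-open) for amplicons or disparity regions.

    Accepts ``Amplicon`` or ``DisparityRegion`` objects; score column carries
    the run mean log2 (amplicons) or -log10 adjusted p (regions).
    """
    lines = [f"# {header_comment}"] if header_comment else ["# lineamp intervals"]
    rows = []
    for iv in intervals:
        if isinstance(iv, Amplicon):
            rows.append((iv.chrom, iv.start_bp, iv.end_bp, "amplicon", iv.mean_log2))
        elif isinstance(iv, DisparityRegion):
            name = f"{'gain' if iv.direction_state > 0 else 'loss'}_in_{iv.direction_cohort}"
            score = -np.log10(max(iv.bh_p, 1e-300))
            rows.append((iv.chrom, iv.start_bp, iv.end_bp, name, score))
        else:
            chrom, start, end, name, score = iv
            rows.append((chrom, start, end, name, score))
    rows.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, end, name, score in rows:
        if not start < end:
            raise FormatError(f"interval {chrom}:{start}-{end} has start >= end")
        lines.append(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\t{_fmt(score)}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_regions_tsv(regions: list[DisparityRegion], path: str | Path) -> None:
    cols = ["chrom", "start", "end", "n_clones",
            "gain_a", "neutral_a", "loss_a", "gain_b", "neutral_b", "loss_b",
            "fisher_p", "bh_p", "direction", "cohort", "freq_a", "freq_b"]
    lines = ["\t".join(cols)]
    for r in regions:
        t = r.table
        lines.append("\t".join(map(_fmt, [
            r.chrom, r.start_bp, r.end_bp, len(r.clone_indices),
            t[0, 0], t[1, 0], t[2, 0], t[0, 1], t[1, 1], t[2, 1],
            r.fisher_p, r.bh_p,
            "gain" if r.direction_state > 0 else "loss", r.direction_cohort,
            r.freq_a, r.freq_b,
        ])))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_regions_tsv(path: str | Path) -> list[DisparityRegion]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(DisparityRegion(
            chrom=str(r["chrom"]), start_bp=int(r["start"]), end_bp=int(r["end"]),
            clone_indices=np.arange(int(r["n_clones"])),
            table=np.array([[r["gain_a"], r["gain_b"]],
                            [r["neutral_a"], r["neutral_b"]],
                            [r["loss_a"], r["loss_b"]]], dtype=int),
            fisher_p=float(r["fisher_p"]), bh_p=float(r["bh_p"]),
            direction_state=1 if r["direction"] == "gain" else -1,
            direction_cohort=str(r["cohort"]),
            freq_a=float(r["freq_a"]), freq_b=float(r["freq_b"]),
        ))
    return out


def write_regions_audit(regions: list[DisparityRegion], path: str | Path) -> None:
    payload = [{
        "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
        "clone_indices": [int(i) for i in r.clone_indices],
        "table": [[int(v) for v in row] for row in r.table],
        "fisher_p": float(r.fisher_p), "bh_p": float(r.bh_p),
        "direction_state": int(r.direction_state),
        "direction_cohort": r.direction_cohort,
        "freq_a": float(r.freq_a), "freq_b": float(r.freq_b),
    } for r in regions]
    atomic_write_text(path, json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    text = df.to_csv(sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    atomic_write_text(path, text)


def write_labels(cohorts: pd.Series, path: str | Path) -> None:
    lines = ["sample\tcohort"] + [f"{s}\t{c}" for s, c in cohorts.items()]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["cohort"].to_numpy(), index=df["sample"])


def write_expression(values: pd.DataFrame, probe_map: pd.DataFrame,
                     prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_table(values, prefix.with_suffix(".tsv"), index_label="probe_id")
    write_table(probe_map.set_index("probe_id"),
                Path(str(prefix) + "_probe_map.tsv"), index_label="probe_id")


def read_expression(values_path, probe_map_path, labels_path, scale="log10"):
    from .integration import ExpressionMatrix
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    probe_map = pd.read_csv(probe_map_path, sep="\t")
    cohorts = read_labels(labels_path)
    return ExpressionMatrix(values=values, probe_map=probe_map,
                            cohorts=cohorts, scale=scale)


# ---------------------------------------------------------------------------
# configuration

_CONFIG_SECTIONS = ("simulation", "qc", "segmentation", "amplification",
                    "comparison", "integration", "sam", "paths", "seed")


def load_config(path: str | Path) -> dict:
    """Load a pipeline YAML config; unknown top-level keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise FormatError(f"unknown config sections: {sorted(unknown)}")
    return raw


def dump_config(cfg: dict, path: str | Path) -> None:
    atomic_write_text(path, yaml.safe_dump(cfg, sort_keys=True))
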