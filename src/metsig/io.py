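"""Readers and writers for the pipeline's plain-text formats.

TSV throughout (tab-separated, header row, UTF-8, '.' decimal). Expression
matrices have a leading ``gene`` column; probe tracks and gene models use
0-based half-open coordinates; segments are emitted in IGV SEG column order.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import (
    InputError,
    PairedExpressionCohort,
    ProbeTrack,
    SegmentSet,
    Signature,
    SignatureGene,
    SurvivalCohort,
)


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed TSV {path}: {exc}") from exc
    return df


def write_expression(values: pd.DataFrame, path) -> None:
    out = values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise InputError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate gene ids {dupes[:5]}")
    return df


def write_sample_map(sample_map: pd.DataFrame, path) -> None:
    out = sample_map.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_sample_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("sample", "case", "tissue"):
        if col not in df.columns:
            raise InputError(f"{path}: sample map missing column {col!r}")
    return df.set_index("sample")


def write_cohort(cohort: PairedExpressionCohort, expr_path, map_path) -> None:
    write_expression(cohort.values, expr_path)
    write_sample_map(cohort.sample_map, map_path)


def read_cohort(expr_path, map_path) -> PairedExpressionCohort:
    return PairedExpressionCohort(
        values=read_expression(expr_path), sample_map=read_sample_map(map_path)
    )


def write_clinical(cohort: SurvivalCohort, path) -> None:
    out = cohort.clinical.copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "patient" not in df.columns:
        raise InputError(f"{path}: clinical table missing 'patient' column")
    if df["patient"].duplicated().any():
        raise InputError(f"{path}: duplicate patient ids")
    return df.set_index("patient")


def read_survival(clinical_path, expr_path=None) -> SurvivalCohort:
    clinical = read_clinical(clinical_path)
    expression = read_expression(expr_path) if expr_path else None
    if expression is not None:
        missing = set(clinical.index) - set(expression.columns)
        if missing:
            raise InputError(
                f"patients missing from expression matrix: {sorted(missing)[:5]}"
            )
        expression = expression[list(clinical.index)]
    return SurvivalCohort(clinical=clinical, expression=expression)


def write_probe_track(track: ProbeTrack, path) -> None:
    track.probes.to_csv(path, sep="\t", index=False)


def read_probe_track(path) -> ProbeTrack:
    return ProbeTrack(probes=_read_tsv(path))


def write_segments(segments: SegmentSet, path, sample: str = "sample") -> None:
    """IGV SEG order: sample, chrom, start, end, n_probes, seg.mean."""
    out = segments.segments.copy()
    out.insert(0, "sample", sample)
    out = out.rename(columns={"mean": "seg.mean", "n_probes": "num.probes"})
    out.to_csv(path, sep="\t", index=False)


def read_segments(path) -> SegmentSet:
    df = _read_tsv(path)
    df = df.rename(columns={"seg.mean": "mean", "num.probes": "n_probes"})
    return SegmentSet(segments=df[["chrom", "start", "end", "n_probes", "mean"]])


def read_gene_bed(path) -> pd.DataFrame:
    """BED4: chrom, start, end, name (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        comment="#",
    )
    return df


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_signature(sig: Signature, path) -> None:
    data = {
        "genes": [{"gene": g.gene, "met_direction": g.met_direction} for g in sig.genes],
        "high_risk_threshold": sig.high_risk_threshold,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_signature(path) -> Signature:
    data = json.loads(Path(path).read_text())
    return Signature(
        genes=[SignatureGene(g["gene"], g["met_direction"]) for g in data["genes"]],
        high_risk_threshold=data["high_risk_threshold"],
    )


def write_risk(risk, path) -> None:
    out = risk.table.copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
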