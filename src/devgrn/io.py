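"""Readers and writers for the pipeline's plain-text interchange formats.

Expression, metadata and annotation tables are UTF-8 TSV with a one-line
header; edge lists, predictions and evaluation summaries are CSV.  Floats in
expression files are written with 17 significant digits so a write/read
round trip is bitwise exact; prediction confidences are printed with 6
significant digits.  Lines starting with ``#`` are treated as comments on
read (the CLI prepends a parameter-echo header to its outputs).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MAX_PREDICTIONS_PER_TARGET,
    EdgeList,
    ExpressionMatrix,
    GeneAnnotation,
    PredictionTable,
    SampleMetadata,
    ValidationError,
    validate_pair,
    warn,
)


class ParseError(ValueError):
    """A cell could not be parsed; the message names its row and column."""


def read_expression(path, metadata_path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read a gene x sample TSV and its sample metadata TSV as a validated pair.

    The first column of the expression file holds gene IDs, the header row
    sample IDs.  Metadata columns: sample_id, time_hpf, series_id, replicate.
    Row and column order are preserved.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        # locate the offending cell to name it in the error
        for col in raw.columns:
            for gene, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell at row {gene!r}, column {col!r}: {cell!r}"
                    ) from None
        raise
    values.index.name = None
    expr = ExpressionMatrix(values)
    meta = read_metadata(metadata_path)
    validate_pair(expr, meta)
    return expr, meta


def read_metadata(path) -> SampleMetadata:
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"sample_id": str, "series_id": str},
    )
    table["time_hpf"] = table["time_hpf"].astype(float)
    table["replicate"] = table["replicate"].astype(int)
    return SampleMetadata(table)


def write_expression(expr: ExpressionMatrix, path, meta: SampleMetadata | None = None,
                     metadata_path=None) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if meta is not None and metadata_path is not None:
        meta.table.to_csv(metadata_path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"transcript_id": str, "gene_id": str})
    for flag in ("is_tf", "is_regulatory_go"):
        if flag in table.columns:
            table[flag] = table[flag].astype(bool)
    return GeneAnnotation(table)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> EdgeList:
    table = pd.read_csv(path, comment="#", dtype={"regulator": str, "target": str})
    if "sign" in table.columns:
        table["sign"] = table["sign"].fillna(0).astype(int)
    return EdgeList(table)


def write_edge_list(edges: EdgeList, path) -> None:
    edges.table.to_csv(path, index=False)


def read_gene_set(path) -> set[str]:
    """One gene ID per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def _sig6(x: float) -> str:
    return f"{x:.6g}"


def write_predictions(preds: PredictionTable, path) -> None:
    """Write a prediction table as regulator,target,confidence CSV.

    Rows are ordered by target then rank.  Refuses tables violating the
    per-target cap of 30 ranked predictions (enforced by the container, and
    re-checked here so a hand-built frame cannot slip through).
    """
    counts = preds.table.groupby("target").size()
    over = counts[counts > MAX_PREDICTIONS_PER_TARGET]
    if len(over):
        raise ValidationError(
            f"target {over.index[0]!r} has {int(over.iloc[0])} predictions "
            f"(max {MAX_PREDICTIONS_PER_TARGET})"
        )
    df = preds.table.sort_values(["target", "rank"])
    with open(path, "w") as fh:
        fh.write("regulator,target,confidence\n")
        for _, row in df.iterrows():
            fh.write(f"{row['regulator']},{row['target']},{_sig6(row['confidence'])}\n")


def read_predictions(path) -> PredictionTable:
    """Read a regulator,target,confidence CSV; ranks are rebuilt per target
    from |confidence| descending (ties: regulator lexicographic)."""
    df = pd.read_csv(path, comment="#", dtype={"regulator": str, "target": str})
    df["confidence"] = df["confidence"].astype(float)
    parts = []
    for _, grp in df.groupby("target", sort=False):
        grp = grp.assign(_abs=grp["confidence"].abs())
        grp = grp.sort_values(["_abs", "regulator"], ascending=[False, True])
        grp = grp.drop(columns="_abs")
        grp["rank"] = np.arange(1, len(grp) + 1)
        parts.append(grp)
    if not parts:
        return empty_predictions()
    return PredictionTable(pd.concat(parts, ignore_index=True))


def empty_predictions() -> PredictionTable:
    return PredictionTable(
        pd.DataFrame(columns=["regulator", "target", "confidence", "rank"])
    )


def map_transcripts_to_genes(expr: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Re-key transcript rows to gene IDs, summing transcripts that share a
    gene and dropping transcripts absent from the annotation.

    Summation conserves total abundance over the mapped transcripts.
    """
    gene_of = ann.gene_of()
    keep = [t for t in expr.gene_ids if t in gene_of.index]
    dropped = len(expr.gene_ids) - len(keep)
    if dropped:
        warn(f"dropping {dropped} transcripts with no annotation record")
    if not keep:
        warn("no transcripts could be mapped; result is empty")
        return ExpressionMatrix(
            pd.DataFrame(columns=expr.data.columns, dtype=float), expr.unit_label
        )
    sub = expr.data.loc[keep]
    collapsed = sub.groupby(gene_of.loc[keep].to_numpy(), sort=False).sum()
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(collapsed, expr.unit_label)


def to_rpkm(counts: ExpressionMatrix, ann: GeneAnnotation, library_sizes) -> ExpressionMatrix:
    """Convert raw counts to reads per kilobase per million mapped reads.

    value' = value / (length_bp/1000) / (library_size/1e6).  ``library_sizes``
    maps sample_id -> positive total mapped reads.
    """
    if "transcript_length_bp" not in ann.table.columns:
        raise ValidationError("annotation has no transcript_length_bp column")
    lengths = ann.table.set_index("transcript_id")["transcript_length_bp"]
    missing = [g for g in counts.gene_ids if g not in lengths.index or
               not math.isfinite(float(lengths.get(g, float("nan"))))]
    if missing:
        raise ValidationError(f"missing transcript length for gene {missing[0]!r}")
    lib = pd.Series(library_sizes, dtype=float)
    absent = [s for s in counts.sample_ids if s not in lib.index]
    if absent:
        raise ValidationError(f"missing library size for sample {absent[0]!r}")
    if (lib <= 0).any():
        raise ValidationError("library sizes must be > 0")
    kb = lengths.loc[counts.gene_ids].astype(float) / 1000.0
    per_million = lib.loc[counts.sample_ids] / 1e6
    values = counts.data.div(kb, axis=0).div(per_million, axis=1)
    return ExpressionMatrix(values, unit_label="RPKM")
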