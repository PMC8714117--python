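"""Consensus DEG statistics, gene-universe filtering and ground-truth curation.

The inference pipeline operates on a gene universe defined upstream by
differential-expression calls (several methods intersected) and a
regulatory-GO filter.  This module computes the per-method overlap summary
(total, unique-to-method, shared-with-any-other, core intersection), applies
gene-set filters to expression matrices, and curates raw benchmark edge
lists into ground-truth networks: self-loops out, signaling-intermediate
edges out, edges touching unmeasured genes out, duplicates collapsed.

A deliberately simple fold-change DEG caller is included for synthetic
fixtures; it does not emulate any published DEG method's statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    EdgeList,
    ExpressionMatrix,
    GroundTruthNetwork,
    ValidationError,
    warn,
)
from ._utils import round_half_up


@dataclass
class OverlapStats:
    """Per-method overlap summary plus the all-methods core intersection size.

    ``per_method`` rows: total, n_unique (present in that method only),
    pct_unique, n_overlap (shared with at least one other method),
    pct_overlap.  Percentages are 100*count/total rounded half-up to 2
    decimals.
    """

    per_method: pd.DataFrame
    core_intersection_size: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_method.copy()
        df.insert(0, "method", df.index)
        return df.reset_index(drop=True)


def overlap_stats(sets: dict[str, set]) -> OverlapStats:
    """Exact set arithmetic over a family of named gene sets."""
    if not sets:
        raise ValidationError("overlap_stats needs at least one set")
    labels = list(sets)
    rows = {}
    for label in labels:
        this = sets[label]
        others = set().union(*(sets[o] for o in labels if o != label)) if len(labels) > 1 else set()
        n_unique = len(this - others)
        n_overlap = len(this) - n_unique
        total = len(this)
        rows[label] = {
            "total": total,
            "n_unique": n_unique,
            "pct_unique": round_half_up(100.0 * n_unique / total, 2) if total else 0.0,
            "n_overlap": n_overlap,
            "pct_overlap": round_half_up(100.0 * n_overlap / total, 2) if total else 0.0,
        }
    core = set(sets[labels[0]])
    for label in labels[1:]:
        core &= sets[label]
    return OverlapStats(pd.DataFrame.from_dict(rows, orient="index"), len(core))


def apply_gene_filter(expr: ExpressionMatrix, keep) -> ExpressionMatrix:
    """Restrict rows to ``keep`` (intersection), preserving row order."""
    keep = set(keep)
    rows = [g for g in expr.gene_ids if g in keep]
    if not rows:
        raise ValidationError("gene filter leaves no rows; pipeline cannot proceed")
    return ExpressionMatrix(expr.data.loc[rows], expr.unit_label)


def curate_ground_truth(raw: EdgeList, measured_genes, drop_signaling: bool = True) -> GroundTruthNetwork:
    """Curate a raw benchmark edge list into a ground-truth network.

    Removes self-edges (the response model cannot represent
    self-regulation), rows whose provenance flags a signaling intermediate
    (when ``drop_signaling``), edges touching genes outside the measured
    universe, and duplicate (regulator, target) pairs (first occurrence
    kept).  Idempotent.
    """
    measured = set(measured_genes)
    df = raw.table.copy()
    df = df[df["regulator"] != df["target"]]
    if drop_signaling and "provenance" in df.columns:
        df = df[df["provenance"].fillna("").str.lower() != "signaling"]
    df = df[df["regulator"].isin(measured) & df["target"].isin(measured)]
    df = df.drop_duplicates(subset=["regulator", "target"], keep="first")
    if df.empty:
        warn("ground-truth curation removed every edge")
    return GroundTruthNetwork(df.reset_index(drop=True))


def fold_change_deg(expr: ExpressionMatrix, log2fc_cutoff: float) -> set[str]:
    """Call a gene differentially expressed if its max-over-time
    |log2((x+1)/(x_ref+1))| meets the cutoff, with the first sample as
    reference.  A stand-in caller for synthetic fixtures only."""
    if expr.shape[1] < 2:
        raise ValidationError("fold_change_deg needs at least 2 samples")
    values = expr.data.to_numpy(dtype=float)
    ref = values[:, [0]]
    lfc = np.abs(np.log2((values + 1.0) / (ref + 1.0)))
    hit = lfc.max(axis=1) >= log2fc_cutoff
    return {g for g, h in zip(expr.gene_ids, hit) if h}
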