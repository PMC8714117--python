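"""Benchmarking predictions against curated ground-truth networks.

An edge "hits" iff its (regulator, target) pair matches a ground-truth row
exactly; matching is directed but sign-blind (sign accuracy is a separate
statistic).  Sensitivity = 100*TP/n_gt, miss rate = 100*(n_gt-TP)/n_gt,
both rounded half-up to 2 decimals; new predictions are edges absent from
the ground truth, and total = TP + new over the full thresholded table.

Spatial co-expression classification labels each predicted edge against a
territory x timepoint presence matrix: "missing" when either gene lacks any
spatial record, "overlapping" when the two genes share at least one
(territory, time) cell, "non-overlapping" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GroundTruthNetwork,
    PredictionTable,
    SampleMetadata,
    ValidationError,
)
from ._utils import round_half_up
from .dynamics import DecayModel
from .regression import PenaltyConfig, infer_network


@dataclass
class EvaluationSummary:
    """Ground-truth comparison statistics for one prediction set."""

    n_gt_edges: int
    true_predictions: int
    sensitivity_pct: float
    miss_rate_pct: float
    new_predicted_edges: int
    total_predictions: int

    def to_dict(self) -> dict:
        return {
            "n_gt_edges": self.n_gt_edges,
            "true_predictions": self.true_predictions,
            "sensitivity_pct": self.sensitivity_pct,
            "miss_rate_pct": self.miss_rate_pct,
            "new_predicted_edges": self.new_predicted_edges,
            "total_predictions": self.total_predictions,
        }


def evaluate(preds: PredictionTable, gt: GroundTruthNetwork) -> EvaluationSummary:
    """Directed, sign-blind comparison of a prediction table with a curated
    ground truth.  Predicted edges must be unique (the container enforces
    this; a raw frame with duplicates is rejected)."""
    pred_pairs = list(zip(preds.table["regulator"], preds.table["target"]))
    if len(pred_pairs) != len(set(pred_pairs)):
        raise ValidationError("duplicate predicted edges; deduplicate first")
    gt_pairs = gt.pairs()
    n_gt = len(gt_pairs)
    tp = sum(1 for p in pred_pairs if p in gt_pairs)
    new = len(pred_pairs) - tp
    if n_gt:
        sens = round_half_up(100.0 * tp / n_gt, 2)
        miss = round_half_up(100.0 * (n_gt - tp) / n_gt, 2)
    else:
        sens, miss = 0.0, 0.0
    return EvaluationSummary(n_gt, tp, sens, miss, new, tp + new)


def sign_agreement(preds: PredictionTable, gt: GroundTruthNetwork,
                   top_k: int = 5) -> float | None:
    """Percent of matched edges (rank <= top_k, ground-truth sign known)
    whose predicted sign agrees; None when no edge is eligible."""
    signs = gt.signs()
    eligible = agree = 0
    for _, row in preds.table.iterrows():
        if row["rank"] > top_k:
            continue
        key = (row["regulator"], row["target"])
        if key not in signs:
            continue
        eligible += 1
        pred_sign = 1 if row["confidence"] > 0 else -1
        if pred_sign == signs[key]:
            agree += 1
    if eligible == 0:
        return None
    return round_half_up(100.0 * agree / eligible, 2)


def half_life_sweep(expr: ExpressionMatrix, meta: SampleMetadata, tf_ids,
                    gt: GroundTruthNetwork, h_list, cfg: PenaltyConfig,
                    peak_value: float = 0.0) -> pd.DataFrame:
    """Run the full inference once per candidate half-life (hours) with an
    identical configuration and seed; one summary row per half-life."""
    h_list = list(h_list)
    if not h_list:
        raise ValidationError("h_list must be non-empty")
    if any(h <= 0 for h in h_list):
        raise ValidationError("half-lives must be positive")
    rows = []
    for h in h_list:
        preds = infer_network(expr, meta, tf_ids, DecayModel(h), cfg, peak_value)
        summary = evaluate(preds, gt)
        rows.append({"half_life_h": h, **summary.to_dict()})
    return pd.DataFrame(rows)


def rank_enrichment_p(preds: PredictionTable, gt: GroundTruthNetwork,
                      n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Permutation test: do ground-truth edges rank better than chance?

    The statistic is the mean per-target rank of predicted edges that match
    the ground truth; the null reassigns ranks uniformly within each
    target's list.  Returns (observed mean rank, one-sided p-value with the
    add-one correction).  Targets with a single prediction carry no rank
    information and are skipped.
    """
    gt_pairs = gt.pairs()
    observed: list[int] = []
    groups: list[tuple[int, int]] = []
    for target, grp in preds.table.groupby("target"):
        k = len(grp)
        hits = [int(r) for r, reg in zip(grp["rank"], grp["regulator"])
                if (reg, target) in gt_pairs]
        if hits and k > 1:
            observed.extend(hits)
            groups.append((k, len(hits)))
    if not observed:
        return float("nan"), 1.0
    obs_mean = float(np.mean(observed))
    rng = np.random.default_rng(seed)
    at_or_below = 0
    for _ in range(n_perm):
        draws = [v for k, m in groups
                 for v in rng.choice(np.arange(1, k + 1), size=m, replace=False)]
        if np.mean(draws) <= obs_mean:
            at_or_below += 1
    return obs_mean, (1 + at_or_below) / (n_perm + 1)


class SpatialMatrix:
    """Gene -> set of (territory_id, time_hpf) presence cells.

    Genes absent from the matrix have unknown spatial expression.  Built
    from a long-format table with columns gene_id, territory_id, time_hpf.
    """

    def __init__(self, cells: dict[str, set[tuple[str, float]]]):
        self.cells = {g: set(c) for g, c in cells.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpatialMatrix":
        cells: dict[str, set] = {}
        for _, row in df.iterrows():
            cells.setdefault(str(row["gene_id"]), set()).add(
                (str(row["territory_id"]), float(row["time_hpf"])))
        return cls(cells)

    @classmethod
    def read(cls, path) -> "SpatialMatrix":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def write(self, path) -> None:
        rows = [
            {"gene_id": g, "territory_id": terr, "time_hpf": t}
            for g in sorted(self.cells)
            for terr, t in sorted(self.cells[g])
        ]
        pd.DataFrame(rows, columns=["gene_id", "territory_id", "time_hpf"]).to_csv(
            path, index=False)

    def known(self, gene: str) -> bool:
        return gene in self.cells and len(self.cells[gene]) > 0


SPATIAL_LABELS = ("overlapping", "non-overlapping", "missing")


def spatial_classify(edge: tuple[str, str], sm: SpatialMatrix) -> str:
    """Label one (regulator, target) edge against the territory matrix."""
    reg, tgt = edge
    if not sm.known(reg) or not sm.known(tgt):
        return "missing"
    if sm.cells[reg] & sm.cells[tgt]:
        return "overlapping"
    return "non-overlapping"


def spatial_summary(preds: PredictionTable, sm: SpatialMatrix, k: int = 50,
                    end: str = "top") -> pd.DataFrame:
    """Classify the k highest- (or lowest-) confidence predictions.

    Returns one row per label with count and 100*count/k.
    """
    if end not in ("top", "bottom"):
        raise ValidationError("end must be 'top' or 'bottom'")
    ordered = preds.sorted_by_confidence()
    if k > len(ordered):
        raise ValidationError(f"k={k} exceeds {len(ordered)} predictions")
    chosen = ordered.head(k) if end == "top" else ordered.tail(k)
    counts = {label: 0 for label in SPATIAL_LABELS}
    for _, row in chosen.iterrows():
        counts[spatial_classify((row["regulator"], row["target"]), sm)] += 1
    return pd.DataFrame(
        [
            {"label": label, "count": counts[label],
             "pct": round_half_up(100.0 * counts[label] / k, 2)}
            for label in SPATIAL_LABELS
        ]
    )
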