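"""Constructed worked-example fixtures and the paired synthetic fixture suite.

The worked-example constructors build, by exact combinatorics, small inputs
whose summary statistics are known in advance: a five-method DEG set family
with prescribed per-method totals and unique counts, prediction/ground-truth
pairs with a prescribed number of hits, and a spatial fixture with a
prescribed label composition.  They let the evaluation arithmetic be
exercised end to end on data with hand-checkable answers.
"""

from __future__ import annotations

import heapq
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EdgeList, GroundTruthNetwork, PredictionTable, ValidationError
from .evaluate import SpatialMatrix
from .io import write_edge_list, write_expression, write_gene_set, write_predictions
from .simulate import SimulationConfig, sample_network, simulate

# per-method (total, unique-to-method) for the five-caller DEG consensus
# family, plus the size of the all-method core intersection
DEG_FAMILY_SPEC = {
    "NOISeq_0.9": (15496, 2),
    "NOISeq_0.85": (16996, 411),
    "GFold_1": (17046, 16),
    "GFold_1.5": (12950, 0),
    "EdgeR": (19166, 988),
}
DEG_CORE_SIZE = 10627


def deg_set_family(spec: dict[str, tuple[int, int]] | None = None,
                   core_size: int = DEG_CORE_SIZE) -> dict[str, set[str]]:
    """Construct named gene sets with exact per-method totals and unique counts.

    Every method contains a shared core (the all-method intersection); each
    method's remaining overlap quota is filled with genes shared by exactly
    two methods (greedy largest-remaining pairing), and its unique quota
    with genes private to it.  Infeasible quotas raise.
    """
    spec = dict(spec or DEG_FAMILY_SPEC)
    labels = list(spec)
    extras = {}
    for label, (total, unique) in spec.items():
        extra = total - unique - core_size
        if extra < 0:
            raise ValidationError(f"{label}: total < unique + core")
        extras[label] = extra
    if sum(extras.values()) % 2 or (len(labels) > 1 and
                                    max(extras.values()) > sum(extras.values()) - max(extras.values())):
        raise ValidationError("pairwise-overlap quotas are infeasible")

    sets: dict[str, set[str]] = {label: set() for label in labels}
    core = {f"c{i:05d}" for i in range(core_size)}
    for label in labels:
        sets[label] |= core
        sets[label] |= {f"u_{label}_{i:04d}" for i in range(spec[label][1])}

    heap = [(-extras[label], label) for label in labels if extras[label] > 0]
    heapq.heapify(heap)
    pair_id = 0
    while heap:
        n1, l1 = heapq.heappop(heap)
        if not heap:
            raise ValidationError("pairwise-overlap quotas are infeasible")
        n2, l2 = heapq.heappop(heap)
        gene = f"p{pair_id:05d}"
        pair_id += 1
        sets[l1].add(gene)
        sets[l2].add(gene)
        if n1 + 1 < 0:
            heapq.heappush(heap, (n1 + 1, l1))
        if n2 + 1 < 0:
            heapq.heappush(heap, (n2 + 1, l2))
    return sets


def benchmark_fixture(n_gt: int, n_hits: int, n_new: int,
                      signed: bool = False) -> tuple[PredictionTable, GroundTruthNetwork]:
    """A ground truth of ``n_gt`` edges and a prediction table containing
    exactly ``n_hits`` of them plus ``n_new`` novel edges.

    Edges use disjoint targets, so every per-target rank is 1; confidences
    decrease across rows (hits first), alternating sign when ``signed``.
    """
    if n_hits > n_gt:
        raise ValidationError("n_hits cannot exceed n_gt")
    gt_rows = [
        {"regulator": f"r{i:04d}", "target": f"t{i:04d}",
         "sign": (1 if i % 2 == 0 else -1) if signed else 0}
        for i in range(n_gt)
    ]
    gt = GroundTruthNetwork(pd.DataFrame(gt_rows))

    total = n_hits + n_new
    conf = np.linspace(0.99, 0.01, total) if total else np.array([])
    rows = []
    for i in range(n_hits):
        sign = (1 if i % 2 == 0 else -1) if signed else 1
        rows.append({"regulator": f"r{i:04d}", "target": f"t{i:04d}",
                     "confidence": sign * conf[i], "rank": 1})
    for j in range(n_new):
        rows.append({"regulator": f"nr{j:04d}", "target": f"nt{j:04d}",
                     "confidence": conf[n_hits + j], "rank": 1})
    preds = PredictionTable(
        pd.DataFrame(rows, columns=["regulator", "target", "confidence", "rank"]))
    return preds, gt


def spatial_fixture(n_overlapping: int = 21, n_non_overlapping: int = 5,
                    n_missing: int = 24) -> tuple[PredictionTable, SpatialMatrix]:
    """A prediction set and territory matrix with an exact label composition.

    Overlapping pairs share one (territory, time) cell; non-overlapping
    pairs are both recorded but in disjoint cells; missing pairs have an
    unrecorded target gene.  Confidences decrease in the order listed so the
    top-k selection reproduces the composition.
    """
    total = n_overlapping + n_non_overlapping + n_missing
    conf = np.linspace(0.95, 0.05, total)
    rows, cells = [], {}
    i = 0
    for j in range(n_overlapping):
        a, b = f"ovA{j:02d}", f"ovB{j:02d}"
        cells[a] = {("aboral_ectoderm", 24.0), ("oral_ectoderm", float(2 * j % 30))}
        cells[b] = {("aboral_ectoderm", 24.0)}
        rows.append({"regulator": a, "target": b, "confidence": conf[i], "rank": 1})
        i += 1
    for j in range(n_non_overlapping):
        a, b = f"noA{j:02d}", f"noB{j:02d}"
        cells[a] = {("pmc", 18.0)}
        cells[b] = {("endoderm", 30.0)}
        rows.append({"regulator": a, "target": b, "confidence": conf[i], "rank": 1})
        i += 1
    for j in range(n_missing):
        a, b = f"msA{j:02d}", f"msB{j:02d}"
        cells[a] = {("veg2", 12.0)}  # regulator known, target absent
        rows.append({"regulator": a, "target": b, "confidence": conf[i], "rank": 1})
        i += 1
    preds = PredictionTable(
        pd.DataFrame(rows, columns=["regulator", "target", "confidence", "rank"]))
    return preds, SpatialMatrix(cells)


def dense_fixture(seed: int = 1, noise_cv: float = 0.1):
    """30-gene / 10-TF dense-schedule dataset (2 h sampling, duplicates)."""
    cfg = SimulationConfig(n_genes=30, n_tfs=10, schedule="dense2h",
                           duplicates=True, noise_cv=noise_cv, seed=seed)
    net = sample_network(cfg)
    expr, meta, truth = simulate(net, cfg)
    return expr, meta, truth, net, cfg


def sparse_fixture(seed: int = 1, noise_cv: float = 0.1):
    """20-gene / 8-TF sparse 10-timepoint dataset (single replicate)."""
    cfg = SimulationConfig(n_genes=20, n_tfs=8, schedule="sparse10",
                           duplicates=False, noise_cv=noise_cv, seed=seed)
    net = sample_network(cfg)
    expr, meta, truth = simulate(net, cfg)
    return expr, meta, truth, net, cfg


def sweep_fixture(seed: int = 1, half_life_h: float = 6.0, noise_cv: float = 0.1):
    """Dense dataset in which every transcript decays with the same known
    half-life, for half-life sweep studies."""
    cfg = SimulationConfig(n_genes=30, n_tfs=10, schedule="dense2h",
                           duplicates=True, noise_cv=noise_cv, seed=seed,
                           half_life_range=(half_life_h, half_life_h))
    net = sample_network(cfg)
    expr, meta, truth = simulate(net, cfg)
    return expr, meta, truth, net, cfg


def make_fixture_suite(out_dir, seed: int = 1) -> dict[str, Path]:
    """Write the paired fixture files used by the acceptance checks.

    (a) dense 30-gene/10-TF dataset + truth; (b) sparse 20-gene dataset +
    truth; (c) benchmark worked examples (76-edge ground truth with 54/530
    and 62/788 prediction mixes); (d) spatial fixture with a 21/5/24 label
    composition over 50 edges; (e) the five-method DEG set family.
    Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for tag, maker in (("dense", dense_fixture), ("sparse", sparse_fixture)):
        expr, meta, truth, net, _ = maker(seed=seed)
        paths[f"{tag}_expr"] = out / f"{tag}_expr.tsv"
        paths[f"{tag}_meta"] = out / f"{tag}_meta.tsv"
        paths[f"{tag}_truth"] = out / f"{tag}_truth.csv"
        paths[f"{tag}_tfs"] = out / f"{tag}_tfs.txt"
        write_expression(expr, paths[f"{tag}_expr"], meta, paths[f"{tag}_meta"])
        write_edge_list(truth, paths[f"{tag}_truth"])
        write_gene_set(net.tf_ids, paths[f"{tag}_tfs"])

    for tag, (hits, new) in (("54of76", (54, 530)), ("62of76", (62, 788))):
        preds, gt = benchmark_fixture(76, hits, new)
        paths[f"gt76_{tag}"] = out / f"gt76_{tag}.csv"
        paths[f"preds_{tag}"] = out / f"preds_{tag}.csv"
        write_edge_list(EdgeList(gt.table.assign(provenance="fixture")), paths[f"gt76_{tag}"])
        write_predictions(preds, paths[f"preds_{tag}"])

    preds, sm = spatial_fixture()
    paths["spatial_preds"] = out / "spatial_preds.csv"
    paths["spatial_matrix"] = out / "spatial_matrix.csv"
    write_predictions(preds, paths["spatial_preds"])
    sm.write(paths["spatial_matrix"])

    for label, genes in deg_set_family().items():
        paths[f"deg_{label}"] = out / f"deg_{label}.txt"
        write_gene_set(genes, paths[f"deg_{label}"])
    return paths
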