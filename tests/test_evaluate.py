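import numpy as np
import pandas as pd
import pytest

from devgrn.containers import GroundTruthNetwork, PredictionTable, ValidationError
from devgrn.dynamics import DecayModel
from devgrn.evaluate import (
    SpatialMatrix,
    evaluate,
    half_life_sweep,
    rank_enrichment_p,
    sign_agreement,
    spatial_classify,
    spatial_summary,
)
from devgrn.fixtures import benchmark_fixture, spatial_fixture
from devgrn.preprocess import curate_ground_truth
from devgrn.regression import PenaltyConfig
from devgrn.simulate import SimulationConfig, sample_network, simulate


class TestEvaluate:
    @pytest.mark.parametrize("n_gt,hits,new,sens,miss,total", [
        (76, 54, 530, 71.05, 28.95, 584),    # sparse course vs ectoderm benchmark
        (115, 74, 1103, 64.35, 35.65, 1177),  # sparse course vs endomesoderm
        (61, 44, 508, 72.13, 27.87, 552),     # dense course vs ectoderm
        (76, 62, 788, 81.58, 18.42, 850),     # dense course vs endomesoderm
    ])
    def test_benchmark_arithmetic(self, n_gt, hits, new, sens, miss, total):
        preds, gt = benchmark_fixture(n_gt, hits, new)
        s = evaluate(preds, gt)
        assert s.true_predictions == hits
        assert s.sensitivity_pct == sens
        assert s.miss_rate_pct == miss
        assert s.new_predicted_edges == new
        assert s.total_predictions == total

    def test_empty_predictions(self):
        preds, gt = benchmark_fixture(10, 0, 0)
        s = evaluate(preds, gt)
        assert (s.true_predictions, s.sensitivity_pct, s.new_predicted_edges) == (0, 0.0, 0)

    def test_perfect_predictions(self):
        preds, gt = benchmark_fixture(12, 12, 0)
        s = evaluate(preds, gt)
        assert s.sensitivity_pct == 100.00
        assert s.miss_rate_pct == 0.00
        assert s.new_predicted_edges == 0

    def test_tp_plus_new_equals_total_always(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_gt = int(rng.integers(1, 40))
            hits = int(rng.integers(0, n_gt + 1))
            new = int(rng.integers(0, 60))
            preds, gt = benchmark_fixture(n_gt, hits, new)
            s = evaluate(preds, gt)
            assert s.true_predictions + s.new_predicted_edges == len(preds)

    def test_matches_nested_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            gt_rows = {(f"r{rng.integers(0, 20)}", f"t{rng.integers(0, 20)}")
                       for _ in range(rng.integers(1, 30))}
            gt = GroundTruthNetwork(pd.DataFrame(
                [{"regulator": a, "target": b} for a, b in gt_rows]))
            pred_pairs = sorted({(f"r{rng.integers(0, 25)}", f"t{rng.integers(0, 25)}")
                                 for _ in range(rng.integers(1, 40))})
            rows, seen = [], {}
            for a, b in pred_pairs:
                rank = seen.get(b, 0) + 1
                if rank > 30:
                    continue
                seen[b] = rank
                rows.append({"regulator": a, "target": b,
                             "confidence": 0.5 / rank, "rank": rank})
            preds = PredictionTable(pd.DataFrame(rows))
            tp_oracle = 0
            for a, b in preds.pairs():
                for a2, b2 in gt.pairs():
                    if a == a2 and b == b2:
                        tp_oracle += 1
            assert evaluate(preds, gt).true_predictions == tp_oracle

    def test_adding_a_ground_truth_edge_never_lowers_sensitivity(self):
        preds, gt = benchmark_fixture(20, 9, 15)
        base = evaluate(preds, gt).sensitivity_pct
        missing = sorted(gt.pairs() - preds.pairs())[0]
        extra = preds.table.copy()
        extra = pd.concat([extra, pd.DataFrame([{
            "regulator": missing[0], "target": missing[1],
            "confidence": 0.001, "rank": 1}])], ignore_index=True)
        more = evaluate(PredictionTable(extra), gt)
        assert more.sensitivity_pct >= base


class TestSignAgreement:
    def test_three_of_four_agree(self):
        preds, gt = benchmark_fixture(4, 4, 0, signed=True)
        flipped = preds.table.copy()
        flipped.loc[0, "confidence"] *= -1  # break one matched sign
        assert sign_agreement(PredictionTable(flipped), gt) == 75.0

    def test_all_agree(self):
        preds, gt = benchmark_fixture(5, 5, 0, signed=True)
        assert sign_agreement(preds, gt) == 100.0

    def test_unknown_signs_not_applicable(self):
        preds, gt = benchmark_fixture(5, 5, 0, signed=False)
        assert sign_agreement(preds, gt) is None

    def test_rank_cutoff_restricts_eligible_edges(self):
        # one target with 7 ranked regulators; only the rank-7 edge matches
        # the signed ground truth, so top-5 agreement has no eligible edge
        rows = [{"regulator": f"tf{i}", "target": "g1",
                 "confidence": 0.9 - 0.1 * i, "rank": i + 1} for i in range(7)]
        preds = PredictionTable(pd.DataFrame(rows))
        gt = GroundTruthNetwork(pd.DataFrame(
            [{"regulator": "tf6", "target": "g1", "sign": 1}]))
        assert sign_agreement(preds, gt, top_k=5) is None
        assert sign_agreement(preds, gt, top_k=7) == 100.0


class TestHalfLifeSweep:
    def _data(self):
        cfg = SimulationConfig(n_genes=10, n_tfs=4, schedule="sparse10",
                               duplicates=False, noise_cv=0.05, seed=3)
        net = sample_network(cfg)
        expr, meta, truth = simulate(net, cfg)
        gt = curate_ground_truth(truth, expr.gene_ids)
        return expr, meta, net, gt

    def test_one_row_per_half_life_and_duplicates_identical(self):
        expr, meta, net, gt = self._data()
        table = half_life_sweep(expr, meta, net.tf_ids, gt, [5.0, 9.0, 5.0],
                                PenaltyConfig(seed=1))
        assert len(table) == 3
        first = table.iloc[0].drop("half_life_h")
        dup = table.iloc[2].drop("half_life_h")
        assert first.equals(dup)

    def test_empty_or_invalid_h_list_rejected(self):
        expr, meta, net, gt = self._data()
        with pytest.raises(ValidationError):
            half_life_sweep(expr, meta, net.tf_ids, gt, [], PenaltyConfig(seed=1))
        with pytest.raises(ValidationError):
            half_life_sweep(expr, meta, net.tf_ids, gt, [-2.0], PenaltyConfig(seed=1))


class TestSpatial:
    def test_shared_cell_is_overlapping(self):
        sm = SpatialMatrix({"a": {("oral_ectoderm", 24.0)},
                            "b": {("oral_ectoderm", 24.0), ("pmc", 18.0)}})
        assert spatial_classify(("a", "b"), sm) == "overlapping"

    def test_absent_gene_is_missing(self):
        sm = SpatialMatrix({"a": {("pmc", 18.0)}})
        assert spatial_classify(("a", "zz"), sm) == "missing"

    def test_disjoint_cells_non_overlapping(self):
        sm = SpatialMatrix({"a": {("pmc", 18.0)}, "b": {("endoderm", 30.0)}})
        assert spatial_classify(("a", "b"), sm) == "non-overlapping"

    def test_top50_composition(self):
        preds, sm = spatial_fixture(21, 5, 24)
        table = spatial_summary(preds, sm, k=50, end="top")
        got = dict(zip(table["label"], table["pct"]))
        assert got["overlapping"] == 42.0
        assert got["non-overlapping"] == 10.0
        assert got["missing"] == 48.0

    def test_all_missing(self):
        preds, sm = spatial_fixture(0, 0, 10)
        table = spatial_summary(preds, sm, k=10)
        got = dict(zip(table["label"], table["pct"]))
        assert got["missing"] == 100.0

    def test_counts_match_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        preds, sm = spatial_fixture(int(rng.integers(3, 10)),
                                    int(rng.integers(1, 6)),
                                    int(rng.integers(3, 10)))
        k = len(preds)
        table = spatial_summary(preds, sm, k=k)
        counts = {"overlapping": 0, "non-overlapping": 0, "missing": 0}
        for _, row in preds.table.iterrows():
            counts[spatial_classify((row["regulator"], row["target"]), sm)] += 1
        for _, row in table.iterrows():
            assert row["count"] == counts[row["label"]]

    def test_k_larger_than_predictions_rejected(self):
        preds, sm = spatial_fixture(2, 1, 2)
        with pytest.raises(ValidationError):
            spatial_summary(preds, sm, k=10)


class TestRankEnrichment:
    def test_true_edges_at_top_give_small_p(self):
        rows = []
        for t in range(8):
            for rank in range(1, 6):
                rows.append({"regulator": f"tf{rank}", "target": f"g{t}",
                             "confidence": 1.0 - 0.1 * rank, "rank": rank})
        preds = PredictionTable(pd.DataFrame(rows))
        gt = GroundTruthNetwork(pd.DataFrame(
            [{"regulator": "tf1", "target": f"g{t}"} for t in range(8)]))
        obs, p = rank_enrichment_p(preds, gt, n_perm=500, seed=0)
        assert obs == 1.0
        assert p < 0.01

    def test_no_matches_returns_nan(self):
        preds, _ = benchmark_fixture(5, 0, 5)
        gt = GroundTruthNetwork(pd.DataFrame([{"regulator": "x", "target": "y"}]))
        obs, p = rank_enrichment_p(preds, gt)
        assert np.isnan(obs) and p == 1.0
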