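import numpy as np
import pandas as pd
import pytest

from devgrn.containers import PredictionTable, ValidationError
from devgrn.dynamics import DecayModel
from devgrn.regression import (
    PenaltyConfig,
    confidence_scores,
    fit_elastic_net,
    infer_network,
    rank_and_threshold,
)
from devgrn.simulate import SimulationConfig, sample_network, simulate
from devgrn.containers import ExpressionMatrix


def _frame(arr, prefix="tf"):
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFitElasticNet:
    def test_huge_alpha_shrinks_everything_to_zero(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(20, 5)))
        r = rng.normal(size=20)
        cfg = PenaltyConfig(alpha_grid=np.array([1e6, 1e5]), seed=0)
        fit = fit_elastic_net(r, X, cfg)
        assert (fit.coefficients == 0).all()

    def test_tiny_alpha_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        X = _frame(x.reshape(-1, 1))
        r = 2.0 * x
        cfg = PenaltyConfig(alpha_grid=np.array([1e-8, 1e-9]), seed=0)
        fit = fit_elastic_net(r, X, cfg)
        # standardized single-predictor solution is the correlation (= 1 here)
        xs = (x - x.mean()) / x.std()
        rs = (r - r.mean()) / r.std()
        beta_ols = float(np.linalg.lstsq(xs.reshape(-1, 1), rs, rcond=None)[0][0])
        assert fit.coefficients.iloc[0] == pytest.approx(beta_ols, abs=1e-8)
        assert fit.r2_full == pytest.approx(1.0, abs=1e-8)

    def test_informative_predictor_selected_among_irrelevant(self):
        rng = np.random.default_rng(42)
        X = _frame(rng.normal(size=(40, 6)))
        r = 2.0 * X["tf0"].to_numpy() + 0.01 * rng.normal(size=40)
        fit = fit_elastic_net(r, X, PenaltyConfig(seed=1))
        assert fit.coefficients["tf0"] > 0.5
        others = fit.coefficients.drop("tf0").abs()
        assert (others < 0.05).sum() >= 4

    def test_too_few_intervals_rejected(self):
        X = _frame(np.ones((3, 2)))
        with pytest.raises(ValidationError, match="intervals"):
            fit_elastic_net(np.ones(3), X, PenaltyConfig())

    def test_zero_variance_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = _frame(np.column_stack([rng.normal(size=12), np.full(12, 2.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_elastic_net(rng.normal(size=12), X, PenaltyConfig(seed=0))
        assert "tf1" not in fit.coefficients.index
        assert fit.dropped == ["tf1"]


class TestConfidenceScores:
    def test_single_exact_predictor_scores_plus_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=24)
        X = _frame(x.reshape(-1, 1))
        r = 3.0 * x
        cfg = PenaltyConfig(alpha_grid=np.array([1e-8, 1e-9]), seed=0)
        fit = fit_elastic_net(r, X, cfg)
        conf = confidence_scores(r, X, fit)
        assert conf["tf0"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_coefficient_predictors_absent(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(30, 4)))
        r = 2.0 * X["tf2"].to_numpy() + 0.01 * rng.normal(size=30)
        fit = fit_elastic_net(r, X, PenaltyConfig(seed=0))
        conf = confidence_scores(r, X, fit)
        zeroed = [tf for tf in fit.coefficients.index if fit.coefficients[tf] == 0]
        assert all(tf not in conf.index for tf in zeroed)

    def test_orthogonal_equal_predictors_split_the_variance(self):
        n = 32
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)  # orthogonal to x1
        X = _frame(np.column_stack([x1, x2]))
        r = x1 + x2
        cfg = PenaltyConfig(alpha_grid=np.array([1e-7, 1e-8]), seed=0)
        fit = fit_elastic_net(r, X, cfg)
        conf = confidence_scores(r, X, fit)
        assert conf["tf0"] == pytest.approx(0.5, abs=1e-3)
        assert conf["tf1"] == pytest.approx(0.5, abs=1e-3)


class TestRankAndThreshold:
    def test_truncates_to_thirty(self):
        conf = {"g1": pd.Series({f"tf{i:02d}": 0.9 - 0.01 * i for i in range(35)})}
        preds = rank_and_threshold(conf, 0.0)
        assert len(preds) == 30
        assert list(preds.table["rank"]) == list(range(1, 31))

    def test_zero_threshold_keeps_all_nonzero(self):
        conf = {"g1": pd.Series({"tfA": 0.2, "tfB": -0.1})}
        assert len(rank_and_threshold(conf, 0.0)) == 2

    def test_threshold_and_tie_handling(self):
        conf = {"g1": pd.Series({"tfA": 0.9, "tfB": 0.5, "tfC": -0.5})}
        preds = rank_and_threshold(conf, 0.6)
        assert len(preds) == 1
        assert preds.table.iloc[0]["regulator"] == "tfA"
        assert preds.table.iloc[0]["rank"] == 1

    def test_confidence_magnitude_nonincreasing_in_rank(self):
        rng = np.random.default_rng(8)
        conf = {f"g{k}": pd.Series({f"tf{j}": float(c) for j, c in
                                    enumerate(rng.uniform(-1, 1, size=7))})
                for k in range(4)}
        preds = rank_and_threshold(conf, 0.0)
        for _, grp in preds.table.groupby("target"):
            mags = grp.sort_values("rank")["confidence"].abs().to_numpy()
            assert (np.diff(mags) <= 1e-12).all()


def _small_dataset(seed=7, noise=0.0):
    cfg = SimulationConfig(n_genes=12, n_tfs=5, schedule="sparse10",
                           duplicates=False, noise_cv=noise, seed=seed)
    net = sample_network(cfg)
    expr, meta, truth = simulate(net, cfg)
    return expr, meta, net, truth


class TestInferNetwork:
    def test_deterministic_across_runs(self):
        expr, meta, net, _ = _small_dataset()
        a = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), PenaltyConfig(seed=7))
        b = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), PenaltyConfig(seed=7))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_tf_list_gives_empty_table(self):
        expr, meta, _, _ = _small_dataset()
        preds = infer_network(expr, meta, [], DecayModel(7.0), PenaltyConfig(seed=1))
        assert len(preds) == 0

    def test_scale_invariance_of_edge_set_and_ranks(self):
        expr, meta, net, _ = _small_dataset()
        scaled = ExpressionMatrix(expr.data * 3.7, expr.unit_label)
        a = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), PenaltyConfig(seed=7))
        b = infer_network(scaled, meta, net.tf_ids, DecayModel(7.0), PenaltyConfig(seed=7))
        key = ["regulator", "target", "rank"]
        pd.testing.assert_frame_equal(
            a.table[key].sort_values(key).reset_index(drop=True),
            b.table[key].sort_values(key).reset_index(drop=True))

    def test_no_self_edges_in_output(self):
        expr, meta, net, _ = _small_dataset(noise=0.05)
        preds = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), PenaltyConfig(seed=3))
        assert not (preds.table["regulator"] == preds.table["target"]).any()

    def test_repeat_ensemble_is_deterministic(self):
        expr, meta, net, _ = _small_dataset(noise=0.05)
        cfg = PenaltyConfig(seed=2, repeat=3)
        a = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), cfg)
        b = infer_network(expr, meta, net.tf_ids, DecayModel(7.0), cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
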