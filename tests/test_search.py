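import numpy as np
import pandas as pd
import pytest

import tagnet as tg
from tagnet.search import SearchConfig
from tagnet.simulate import six_node_truth
from tests.conftest import sample_cov


class TestStarInitialModel:
    def test_fifteen_parents(self):
        parents = [f"g{i}" for i in range(15)]
        m = tg.star_initial_model("oil_productivity", parents)
        assert len(m.nodes) == 16
        assert len(m.edges) == 15
        assert all(t == "oil_productivity" for _, t in m.edges)
        assert not m.error_covariances

    def test_single_parent_df(self):
        m = tg.star_initial_model("y", ["x"])
        # 2 nodes: 3 moments, 1 edge + 2 variances free
        assert m.degrees_of_freedom() == 0

    def test_eight_parents(self):
        m = tg.star_initial_model("Group3",
                                  [f"Group{k}" for k in (1, 2, 4, 5, 6, 7,
                                                         8, 9)])
        assert len(m.nodes) == 9
        assert len(m.edges) == 8

    def test_usage_errors(self):
        with pytest.raises(ValueError):
            tg.star_initial_model("y", [])
        with pytest.raises(ValueError):
            tg.star_initial_model("y", ["y", "x"])


class TestPruneStep:
    def test_null_edges_removed(self):
        """Star with 3 real parents (effect 0.5) and 2 null parents:
        repeated pruning removes exactly the null edges (20 seeds)."""
        truth = tg.star_initial_model("y", ["x1", "x2", "x3", "x4", "x5"])
        theta = np.array([0.5, 0.5, 0.5, 0.0, 0.0] + [1.0] * 6)
        hits = 0
        for seed in range(20):
            S, _ = sample_cov(truth, theta, 5000, seed)
            fm = tg.fit_model(truth.copy(), S, 5000)
            while True:
                model, deleted, _ = tg.prune_step(fm, 0.01)
                if deleted is None:
                    break
                fm = tg.fit_model(model, S, 5000)
            hits += set(fm.model.edges) == {("x1", "y"), ("x2", "y"),
                                            ("x3", "y")}
        assert hits >= 19

    def test_all_significant_unchanged(self):
        truth = tg.star_initial_model("y", ["x1", "x2"])
        S, _ = sample_cov(truth, np.array([0.7, 0.7, 1, 1, 1]), 5000, 0)
        fm = tg.fit_model(truth, S, 5000)
        model, deleted, _ = tg.prune_step(fm, 0.01)
        assert deleted is None
        assert model is fm.model

    def test_one_at_a_time(self):
        truth = tg.star_initial_model("y", ["x1", "x2", "x3"])
        theta = np.array([0.6, 0.0, 0.0] + [1.0] * 4)
        S, _ = sample_cov(truth, theta, 5000, 4)
        fm = tg.fit_model(truth, S, 5000)
        model, deleted, p = tg.prune_step(fm, 0.01)
        assert deleted is not None
        assert len(model.edges) == 2  # exactly one removed per step


class TestAddStep:
    def test_true_missing_edge_ranks_first(self):
        """Data from x1 -> x2 -> x3 fitted as x1 -> x3 only: the top MI
        candidate involves one of the true missing edges (20 seeds)."""
        truth = tg.PathModel(nodes=["x1", "x2", "x3"])
        truth.add_edge("x1", "x2")
        truth.add_edge("x2", "x3")
        theta = np.array([0.6, 0.6, 1, 1, 1])
        hits = 0
        for seed in range(20):
            S, _ = sample_cov(truth, theta, 5000, seed)
            m = tg.PathModel(nodes=["x1", "x2", "x3"])
            m.add_edge("x1", "x3")
            fm = tg.fit_model(m, S, 5000)
            model, added, mi = tg.add_step(fm, "paths", 3.84)
            if added is not None and set(added[1]) in ({"x1", "x2"},
                                                       {"x2", "x3"}):
                hits += 1
        assert hits >= 18

    def test_below_threshold_unchanged(self):
        truth = tg.star_initial_model("y", ["x1", "x2"])
        S, _ = sample_cov(truth, np.array([0.6, 0.6, 1, 1, 1]), 5000, 2)
        fm = tg.fit_model(truth, S, 5000)
        model, added, _ = tg.add_step(fm, "paths", mi_threshold=1e9)
        assert added is None

    def test_tabu_candidate_skipped(self):
        truth = tg.PathModel(nodes=["x1", "x2", "x3"])
        truth.add_edge("x1", "x2")
        truth.add_edge("x2", "x3")
        S, _ = sample_cov(truth, np.array([0.6, 0.6, 1, 1, 1]), 5000, 3)
        m = tg.PathModel(nodes=["x1", "x2", "x3"])
        m.add_edge("x1", "x3")
        fm = tg.fit_model(m, S, 5000)
        _, added, _ = tg.add_step(fm, "paths", 3.84)
        tabu = {added}
        _, added2, _ = tg.add_step(fm, "paths", 3.84, tabu)
        assert added2 != added


class TestOptimize:
    def test_pure_star_returned_unchanged(self):
        truth = tg.star_initial_model("y", ["x1", "x2", "x3"])
        theta = np.array([0.6, 0.5, 0.4] + [1.0] * 4)
        S, _ = sample_cov(truth, theta, 5000, 0)
        cfg = SearchConfig(restarts=0, seed=0)
        fm, trace, flags = tg.optimize(truth.copy(), S, 5000, cfg)
        assert set(fm.model.edges) == set(truth.edges)
        assert flags.accepted

    def test_six_node_structure_recovery(self):
        """Directed edge recovery F1 >= 0.9 on the benchmark six-node
        model at n = 5000 over 10 seeds."""
        truth, theta = six_node_truth()
        true_edges = set(truth.edges)
        f1s = []
        for seed in range(10):
            _, df = sample_cov(truth, theta, 5000, seed)
            est = tg.StepwiseSEMSearch(objective="y", seed=seed,
                                       restarts=5).fit(df)
            found = set(est.best_model_.edges)
            tp = len(found & true_edges)
            f1s.append(2 * tp / (len(found) + len(true_edges)))
        assert np.mean(f1s) >= 0.9

    def test_trace_replay_reproduces_final_model(self):
        truth, theta = six_node_truth()
        S, _ = sample_cov(truth, theta, 5000, 1)
        cfg = SearchConfig(restarts=1, seed=1)
        fm, trace, _ = tg.optimize(
            tg.star_initial_model("y", ["x1", "x2", "x3", "x4", "x5"]),
            S, 5000, cfg)
        replayed = trace.replay()
        fm2 = tg.fit_model(replayed, S, 5000)
        assert set(replayed.edges) == set(fm.model.edges)
        assert set(replayed.error_covariances) == set(
            fm.model.error_covariances)
        assert fm2.chi2 == pytest.approx(fm.chi2, abs=1e-8)

    def test_no_self_or_duplicate_edges_and_final_significance(self):
        truth, theta = six_node_truth()
        S, _ = sample_cov(truth, theta, 5000, 2)
        cfg = SearchConfig(restarts=1, seed=2)
        fm, trace, flags = tg.optimize(
            tg.star_initial_model("y", ["x1", "x2", "x3", "x4", "x5"]),
            S, 5000, cfg)
        edges = list(fm.model.edges)
        assert len(edges) == len(set(edges))
        assert all(s != t for s, t in edges)
        if flags.all_significant:
            assert all(p < 0.01 for p in fm.structural_pvalues().values())

    def test_aic_not_worse_than_initial_when_accepted(self):
        truth, theta = six_node_truth()
        S, _ = sample_cov(truth, theta, 5000, 3)
        initial = tg.star_initial_model("y", ["x1", "x2", "x3", "x4", "x5"])
        fm0 = tg.fit_model(initial.copy(), S, 5000)
        cfg = SearchConfig(restarts=1, seed=3)
        fm, trace, flags = tg.optimize(initial, S, 5000, cfg)
        took_action = any(a.action in ("delete", "add") for a in trace.actions)
        if flags.accepted and took_action:
            assert fm.fit_report.aic <= fm0.fit_report.aic + 1e-9

    def test_true_strong_edges_rarely_deleted(self):
        """Edges with standardized weight >= 0.4 survive the search in at
        least 95% of seeds at n = 5000."""
        truth, theta = six_node_truth()
        strong = {("x2", "y"), ("x4", "y"), ("x5", "y")}
        lost = 0
        trials = 20
        for seed in range(trials):
            _, df = sample_cov(truth, theta, 5000, 100 + seed)
            est = tg.StepwiseSEMSearch(objective="y", seed=seed,
                                       restarts=2).fit(df)
            found = set(est.best_model_.edges)
            lost += len(strong - found)
        assert lost / (trials * len(strong)) <= 0.05


class TestPipeline:
    def _dataset(self, n, seed, **kw):
        from tagnet.preprocess import AnalysisDataset
        from tagnet.simulate import table1_like_scenario

        expr, truth = table1_like_scenario(n=n, seed=seed, **kw)
        ds = AnalysisDataset(expression=expr,
                             sample_map=pd.DataFrame(index=expr.samples))
        return ds, truth

    def test_missing_oil_productivity_raises(self):
        ds, _ = self._dataset(100, 0)
        ds.data.rename(index={"oil_productivity": "x"}, inplace=True)
        with pytest.raises(ValueError, match="oil_productivity"):
            tg.run_stepwise_pipeline(ds)

    def test_determinism_same_seed_same_trace(self):
        ds, _ = self._dataset(150, 1)
        cfg = SearchConfig(restarts=0, max_iter=15, seed=7)
        r1 = tg.run_stepwise_pipeline(ds, cfg, n_factors=9)
        r2 = tg.run_stepwise_pipeline(ds, cfg, n_factors=9)
        assert r1.group_trace.to_frame().equals(r2.group_trace.to_frame())
        assert r1.pseudo_trace.to_frame().equals(r2.pseudo_trace.to_frame())

    def test_group_level_adjacency_recovery(self):
        """End-to-end: with a known path model coupling the nine factors,
        the group-level model recovers the true adjacencies with skeleton
        F1 >= 0.8 over 10 seeds at n = 500 (orientation at the group level
        is limited by pseudo-variable measurement noise)."""
        from collections import Counter
        from tagnet.simulate import group_network_truth

        tm, ttheta = group_network_truth()
        true_sk = {frozenset(e) for e in tm.edges}
        f1s = []
        for seed in range(10):
            ds, truth = self._dataset(500, seed, loading=0.9,
                                      group_model=tm, group_theta=ttheta)
            cfg = SearchConfig(restarts=2, max_iter=50, seed=seed)
            res = tg.run_stepwise_pipeline(ds, cfg, n_factors=9)
            gt, est = truth.groups, res.groups.factor
            mapping = {
                f"Group{k}":
                f"Group{Counter(gt[est.index[est == k]]).most_common(1)[0][0]}"
                for k in est.unique()}
            found = {frozenset((mapping[s], mapping[t]))
                     for (s, t) in res.pseudo_model.model.edges}
            tp = len(found & true_sk)
            f1s.append(2 * tp / (len(found) + len(true_sk)))
        assert np.mean(f1s) >= 0.8


class TestSearchConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SearchConfig(mi_threshold=0)

    def test_estimator_params_protocol(self):
        est = tg.StepwiseSEMSearch(objective="y")
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05
        with pytest.raises(ValueError):
            est.set_params(junk=1)
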