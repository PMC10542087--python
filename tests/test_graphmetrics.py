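"""Binarisation, graph metrics vs brute-force oracle, AUC and variance tests."""

import numpy as np
import pandas as pd
import pytest

import dfcstates as d
from dfcstates._glm import encode_design, group_t
from _oracles import oracle_bh, oracle_metrics


def _sym(rng, n):
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestBinarize:
    def test_edge_count_and_selection(self, rng):
        z = _sym(rng, 5)
        g = d.binarize_by_sparsity(z, 0.2)  # floor(0.2 * 10) = 2 edges
        assert g.adjacency.sum() // 2 == 2
        iu = np.triu_indices(5, 1)
        kept = np.abs(z[iu])[g.adjacency[iu] == 1].min()
        dropped = np.abs(z[iu])[g.adjacency[iu] == 0].max()
        assert kept >= dropped

    def test_all_equal_weights_lexicographic_ties(self):
        z = np.ones((4, 4)) - np.eye(4)
        g = d.binarize_by_sparsity(z, 0.5)  # floor(0.5 * 6) = 3 edges
        iu = np.triu_indices(4, 1)
        kept_pairs = [(i, j) for i, j in zip(*iu) if g.adjacency[i, j]]
        assert kept_pairs == [(0, 1), (0, 2), (0, 3)]

    def test_unit_sparsity_gives_complete_graph(self, rng):
        z = _sym(rng, 10)
        g = d.binarize_by_sparsity(z, 1.0)
        assert g.adjacency.sum() // 2 == 45
        # floor convention: just below 1.0 drops exactly one edge
        assert d.binarize_by_sparsity(z, 0.9999).adjacency.sum() // 2 == 44

    def test_zero_edge_sparsity_rejected(self, rng):
        with pytest.raises(ValueError, match="zero edges"):
            d.binarize_by_sparsity(_sym(rng, 5), 0.05)

    def test_positive_rank_mode_prefers_positive_edges(self):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = -5.0
        z[2, 3] = z[3, 2] = 0.5
        g_abs = d.binarize_by_sparsity(z, 1 / 6 + 1e-9, rank="abs")
        g_pos = d.binarize_by_sparsity(z, 1 / 6 + 1e-9, rank="positive")
        assert g_abs.adjacency[0, 1] == 1
        assert g_pos.adjacency[2, 3] == 1 and g_pos.adjacency[0, 1] == 0


class TestGraphMetrics:
    def test_complete_graph_closed_form(self):
        adj = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        m = d.graph_metrics(d.BinaryGraph(adj, 1.0))
        np.testing.assert_allclose(m["degree"], 4)
        np.testing.assert_allclose(m["clustering_coefficient"], 1)
        assert m["global_efficiency"] == pytest.approx(1.0)
        np.testing.assert_allclose(m["betweenness"], 0)
        np.testing.assert_allclose(m["local_efficiency"], 1)

    def test_path_graph_known_values(self):
        adj = np.zeros((4, 4), dtype=int)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        m = d.graph_metrics(d.BinaryGraph(adj, 0.5))
        # node 1 lies on shortest paths (0,2) and (0,3) of 3 pairs
        assert m["betweenness"][1] == pytest.approx(2 / 3)
        assert m["nodal_efficiency"][0] == pytest.approx(11 / 18)

    def test_disconnected_pairs_contribute_zero_efficiency(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1  # two isolated dyads
        adj[2, 3] = adj[3, 2] = 1
        m = d.graph_metrics(d.BinaryGraph(adj, 1 / 3))
        np.testing.assert_allclose(m["nodal_efficiency"], 1 / 3)

    def test_oracle_equivalence_on_random_graphs(self, rng):
        # 100 random graphs with N <= 8 against exhaustive path enumeration
        for _ in range(100):
            n = int(rng.integers(3, 9))
            p = rng.uniform(0.2, 0.9)
            adj = (rng.random((n, n)) < p).astype(int)
            adj = np.triu(adj, 1)
            adj += adj.T
            mine = d.graph_metrics(d.BinaryGraph(adj, float(adj.sum())))
            ref = oracle_metrics(adj)
            for name in ref:
                np.testing.assert_allclose(
                    mine[name], ref[name], atol=1e-12,
                    err_msg=f"metric {name} diverges for n={n}",
                )

    def test_global_efficiency_monotone_in_sparsity(self, rng):
        z = _sym(rng, 15)
        prev = -1.0
        for s in d.SparsityLadder().values():
            m = d.graph_metrics(d.binarize_by_sparsity(z, s))
            assert m["global_efficiency"] >= prev - 1e-12
            prev = m["global_efficiency"]


class TestAucAndVariance:
    def test_constant_metric_auc(self):
        ladder = d.SparsityLadder()
        vals = np.ones(31)
        assert d.auc_over_sparsity(vals, ladder) == pytest.approx(0.30)

    def test_linear_ramp_auc(self):
        ladder = d.SparsityLadder()
        vals = np.linspace(0, 1, 31)
        assert d.auc_over_sparsity(vals, ladder) == pytest.approx(0.15, abs=1e-12)

    def test_auc_linearity(self, rng):
        ladder = d.SparsityLadder()
        x, y = rng.random(31), rng.random(31)
        lhs = d.auc_over_sparsity(2.0 * x + 3.0 * y, ladder)
        rhs = 2.0 * d.auc_over_sparsity(x, ladder) + 3.0 * d.auc_over_sparsity(y, ladder)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_missing_rung_rejected(self):
        with pytest.raises(ValueError, match="rungs"):
            d.auc_over_sparsity(np.ones(30), d.SparsityLadder())

    def test_ladder_has_31_rungs_at_defaults(self):
        assert d.SparsityLadder().values().size == 31

    def test_identical_windows_zero_variance(self, rng):
        z = np.repeat(_sym(rng, 10)[None], 4, axis=0)
        auc = d.window_metrics_auc(z, d.SparsityLadder(0.2, 0.3, 0.05))
        var = d.metric_variance(auc)
        assert var["global_efficiency"] == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(var["degree"], 0, atol=1e-20)

    def test_two_window_variance_closed_form(self):
        var = d.metric_variance({"m": np.array([0.1, 0.3])})
        assert var["m"] == pytest.approx(0.02)

    def test_degree_auc_bounded(self, rng):
        z = _sym(rng, 12)
        auc = d.window_metrics_auc(z[None], d.SparsityLadder())
        assert auc["degree"].max() <= 0.30 * 11 + 1e-9

    def test_state_switching_inflates_metric_variance(self):
        # single- vs two-state cohorts at matched noise, with two states
        # whose dense community sits on opposite node blocks so the
        # binarised topology genuinely re-wires at each latent switch
        from dfcstates.simulate import default_transition_matrix

        n = 24
        cov_a = np.eye(n)
        cov_a[:12, :12] = 0.7
        np.fill_diagonal(cov_a, 1.0)
        cov_b = np.eye(n)
        cov_b[12:, 12:] = 0.7
        np.fill_diagonal(cov_b, 1.0)
        ladder = d.SparsityLadder(0.15, 0.35, 0.05)
        spec = d.WindowSpec(30, 5)

        def median_var(n_states, covs, **kw):
            series, _, _ = d.generate_cohort(
                d.CohortConfig(
                    seed=5, n_states=n_states, n_group_a=3, n_group_b=3,
                    n_regions=n, n_volumes=240, state_covariances=covs,
                    noise_sd=0.2, **kw,
                )
            )
            meds = []
            for s in series:
                w = d.windowed_fc(d.preprocess(s, 10, band=None), spec)
                var = d.metric_variance(d.window_metrics_auc(w.z, ladder))
                meds.append(np.median(var["nodal_efficiency"]))
            return np.median(meds)

        mat = default_transition_matrix(2, 0.95)
        two = median_var(
            2, [cov_a, cov_b], transition_matrix_a=mat, transition_matrix_b=mat
        )
        one = median_var(1, [cov_a])
        assert two > one


class TestCompareVariance:
    def _table(self, rng, n_sub=16, n_nodes=8, planted=(), delta=0.0):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_sub)],
                "group": ["patient"] * (n_sub // 2) + ["control"] * (n_sub // 2),
                "age": rng.normal(50, 5, n_sub),
                "sex": rng.choice(["M", "F"], n_sub),
                "education_years": rng.normal(12, 1, n_sub),
            }
        )
        rows = []
        for i in range(n_sub):
            for node in range(n_nodes):
                v = rng.normal(1.0, 0.1)
                if node in planted and i < n_sub // 2:
                    v += delta
                rows.append(
                    {"subject_id": f"s{i}", "metric": "local_efficiency",
                     "node": f"R{node:03d}", "variance": v}
                )
        return pd.DataFrame(rows), meta

    def test_bh_qvalues_match_step_up_oracle(self, rng):
        table, meta = self._table(rng, planted=(0, 1), delta=0.5)
        res = d.compare_variance(table, meta, covariates=())
        q_oracle = oracle_bh(res["p"].to_numpy())
        np.testing.assert_allclose(res["q"].to_numpy(), q_oracle, atol=1e-12)

    def test_worked_bh_example(self):
        np.testing.assert_allclose(
            oracle_bh([0.001, 0.01, 0.02, 0.04]),
            [0.004, 0.02, 0.02 * 4 / 3, 0.04],
            atol=1e-12,
        )

    def test_null_yields_no_discoveries(self, rng):
        fp = 0
        for _ in range(20):
            table, meta = self._table(rng)
            res = d.compare_variance(table, meta, covariates=())
            fp += res["significant"].sum()
        assert fp <= 2  # FDR control: near-zero discoveries under the null

    def test_planted_nodes_discovered(self, rng):
        planted = (0, 1, 2, 3, 4)
        hits = 0
        for _ in range(20):
            table, meta = self._table(rng, n_sub=30, n_nodes=20,
                                      planted=planted, delta=1.0)
            res = d.compare_variance(table, meta, covariates=())
            found = set(res[res["significant"]]["node"])
            if found == {f"R{p:03d}" for p in planted}:
                hits += 1
        assert hits >= 18  # exactly the planted nodes in >= 90% of reps

    def test_global_metric_untouched_by_fdr(self, rng):
        table, meta = self._table(rng)
        gl = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(16)],
                "metric": "global_efficiency",
                "node": "global",
                "variance": rng.normal(1, 0.1, 16),
            }
        )
        res = d.compare_variance(pd.concat([table, gl]), meta, covariates=())
        row = res[res["metric"] == "global_efficiency"].iloc[0]
        assert row["q"] == row["p"]
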