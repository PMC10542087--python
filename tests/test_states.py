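"""Connectivity-state clustering and temporal statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import dfcstates as d
from dfcstates._glm import encode_design, group_t
from dfcstates.simulate import default_transition_matrix
from dfcstates.states import _runs
from _oracles import oracle_pooled_t


def _wfc_from_vecs(vecs, n, sid="s1"):
    z = d.vec_to_matrix(np.asarray(vecs, float), n)
    wins = tuple((i * 3, i * 3 + 30) for i in range(len(vecs)))
    return d.WindowedFC(sid, wins, z, tuple(f"R{i:03d}" for i in range(n)))


class TestFitStates:
    def test_planted_partition_recovered_perfectly(self, rng):
        e = 10  # edges -> N = 5
        a = rng.normal(0.0, 0.01, size=(40, e))
        b = rng.normal(10.0, 0.01, size=(40, e))
        wfc = _wfc_from_vecs(np.vstack([a, b]), 5)
        model = d.fit_states([wfc], k=2, n_restarts=5, seed=0)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, model.labels["s1"]) == 1.0

    def test_k_below_two_rejected(self, small_wfcs):
        with pytest.raises(ValueError):
            d.fit_states(small_wfcs, k=1)

    def test_deterministic_given_seed(self, small_wfcs):
        m1 = d.fit_states(small_wfcs, 3, n_restarts=3, seed=5)
        m2 = d.fit_states(small_wfcs, 3, n_restarts=3, seed=5)
        assert m1.inertia == m2.inertia
        for sid in m1.labels:
            np.testing.assert_array_equal(m1.labels[sid], m2.labels[sid])

    def test_centroids_are_member_means(self, small_wfcs):
        model = d.fit_states(small_wfcs, 3, n_restarts=3, seed=1)
        vecs = np.concatenate([d.upper_vec(w.z) for w in small_wfcs])
        pooled = model.pooled_labels()
        for s in range(1, 4):
            np.testing.assert_allclose(
                model.centroids[s - 1], vecs[pooled == s].mean(axis=0), atol=1e-8
            )

    def test_states_ordered_by_descending_occupancy(self, small_wfcs):
        model = d.fit_states(small_wfcs, 4, n_restarts=3, seed=2)
        pooled = model.pooled_labels()
        counts = [(pooled == s).sum() for s in range(1, 5)]
        assert counts == sorted(counts, reverse=True)


class TestSelectK:
    def test_inertia_strictly_decreasing(self, small_wfcs):
        _, curve, _ = d.select_k(small_wfcs, range(2, 7), seed=0, n_restarts=3)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_single_state_data_flags_flat_curve(self):
        cfg = d.CohortConfig(
            seed=21, n_group_a=4, n_group_b=4, n_regions=16, n_states=1
        )
        series, _, _ = d.generate_cohort(cfg)
        wfcs = [d.windowed_fc(d.preprocess(s, 10), d.WindowSpec(30, 3)) for s in series]
        k, _, flat = d.select_k(wfcs, range(2, 6), seed=0, n_restarts=3)
        assert flat
        assert k == 2

    def test_planted_k_recovered_on_one_cohort(self, small_wfcs):
        k, _, flat = d.select_k(small_wfcs, range(2, 7), seed=3, n_restarts=5)
        assert not flat
        assert k == 4

    def test_silhouette_criterion_available(self, small_wfcs):
        k, curve, _ = d.select_k(
            small_wfcs, range(2, 6), criterion="silhouette", seed=0, n_restarts=3
        )
        assert k in curve
        assert all(-1 <= v <= 1 for v in curve.values())


class TestTemporalMetrics:
    def test_hand_enumerated_example(self):
        tm = d.temporal_metrics({"s": np.array([1, 1, 2, 2, 2, 1])}, k=2)
        row = tm.iloc[0]
        assert row["mdt_1"] == 1.5
        assert row["mdt_2"] == 3.0
        assert row["frac_1"] == 0.5
        assert row["frac_2"] == 0.5
        assert row["n_transitions"] == 2

    def test_constant_sequence(self):
        tm = d.temporal_metrics({"s": np.full(67, 3)}, k=4)
        row = tm.iloc[0]
        assert row["mdt_3"] == 67
        assert row["frac_3"] == 1.0
        assert row["n_transitions"] == 0
        assert row["mdt_1"] == 0.0  # never visited -> zero-inflated MDT

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            d.temporal_metrics({"s": np.array([])}, k=2)

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_run_length_conservation(self, seq):
        # sum over states of MDT[k] * (#runs of k) equals sequence length,
        # and fractional windows sum to 1
        tm = d.temporal_metrics({"s": np.array(seq)}, k=4).iloc[0]
        states, lengths = _runs(np.array(seq))
        total = sum(
            tm[f"mdt_{s}"] * (states == s).sum() for s in range(1, 5)
        )
        assert total == pytest.approx(len(seq), abs=1e-9)
        assert sum(tm[f"frac_{s}"] for s in range(1, 5)) == pytest.approx(1.0, abs=1e-12)

    def test_truth_channel_dwell_matches_geometric_law(self):
        # p_self = 0.8 with tick = window step -> MDT about 5 ticks
        mat = default_transition_matrix(4, 0.8)
        cfg = d.CohortConfig(
            seed=13, n_group_a=15, n_group_b=15, n_regions=8,
            transition_matrix_a=mat, transition_matrix_b=mat,
        )
        _, _, truth = d.generate_cohort(cfg)
        tick_labels = {
            sid: lat[:: cfg.state_switch_step] for sid, lat in truth.latent.items()
        }
        tm = d.temporal_metrics(tick_labels, 4)
        mdt = tm[[f"mdt_{s}" for s in range(1, 5)]].to_numpy()
        assert mdt[mdt > 0].mean() == pytest.approx(5.0, rel=0.10)

    def test_mdt_seconds_conversion(self):
        np.testing.assert_allclose(d.mdt_to_seconds([2.0, 5.0], 3, 2.0), [12.0, 30.0])


class TestCompareTemporal:
    def _metrics_meta(self, rng, n=12, delta=0.0):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n)],
                "group": ["patient"] * n + ["control"] * n,
                "age": rng.normal(50, 8, 2 * n),
                "sex": rng.choice(["M", "F"], 2 * n),
                "education_years": rng.normal(12, 1, 2 * n),
            }
        )
        y = rng.standard_normal(2 * n)
        y[:n] += delta
        metrics = pd.DataFrame({"subject_id": meta["subject_id"], "m": y})
        return metrics, meta

    def test_no_covariates_equals_pooled_t(self, rng):
        metrics, meta = self._metrics_meta(rng, delta=0.8)
        res = d.compare_temporal(metrics, meta, covariates=())
        y = metrics["m"].to_numpy()
        expected = oracle_pooled_t(y[:12], y[12:])
        assert res.iloc[0]["t"] == pytest.approx(expected, abs=1e-10)

    def test_vectorised_glm_matches_compare_temporal(self, rng):
        # the fast GLM path used in simulations must agree to 1e-10
        for _ in range(5):
            metrics, meta = self._metrics_meta(rng, delta=rng.normal())
            res = d.compare_temporal(metrics, meta)
            merged = metrics.merge(meta, on="subject_id")
            x, _ = encode_design(merged, ("age", "sex", "education_years"))
            t, p, _ = group_t(x, merged[["m"]].to_numpy())
            assert res.iloc[0]["t"] == pytest.approx(t[0], abs=1e-10)
            assert res.iloc[0]["p"] == pytest.approx(p[0], abs=1e-10)

    def test_null_type_one_error_calibrated(self, rng):
        # identical groups: rejection rate at alpha = 0.05 over 2000 cohorts
        n = 15
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n)],
                "group": ["patient"] * n + ["control"] * n,
                "age": rng.normal(50, 8, 2 * n),
                "sex": rng.choice(["M", "F"], 2 * n),
                "education_years": rng.normal(12, 1, 2 * n),
            }
        )
        x, _ = encode_design(meta, ("age", "sex", "education_years"))
        y = rng.standard_normal((2 * n, 2000))
        _, p, _ = group_t(x, y)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_collinear_covariate_rejected(self, rng):
        metrics, meta = self._metrics_meta(rng)
        meta["dup"] = (meta["group"] == "patient").astype(float)
        with pytest.raises(ValueError, match="collinear"):
            d.compare_temporal(metrics, meta, covariates=("age", "dup"))

    def test_fewer_than_two_per_group_rejected(self, rng):
        metrics, meta = self._metrics_meta(rng)
        keep = meta["subject_id"] != "s0"
        keep &= meta["subject_id"] != "s1"
        meta2 = meta[~(meta["group"] == "patient") | (meta["subject_id"] == "s2")]
        metrics2 = metrics[metrics["subject_id"].isin(meta2["subject_id"])]
        with pytest.raises(ValueError, match="2 subjects"):
            d.compare_temporal(metrics2, meta2, covariates=())


class TestStateMeanFC:
    def test_single_state_subject(self, small_wfcs):
        w = small_wfcs[0]
        labels = np.ones(w.n_windows, dtype=int)
        mat, visited = d.state_mean_fc(w, labels, 1)
        assert visited
        np.testing.assert_allclose(mat, w.z.mean(axis=0))
        mat2, visited2 = d.state_mean_fc(w, labels, 2)
        assert not visited2 and mat2 is None

    def test_two_window_mean(self):
        z = np.zeros((2, 3, 3))
        z[0, 0, 1] = z[0, 1, 0] = 0.2
        z[1, 0, 1] = z[1, 1, 0] = 0.4
        wfc = d.WindowedFC("s", ((0, 30), (3, 33)), z, ("a", "b", "c"))
        mat, _ = d.state_mean_fc(wfc, np.array([2, 2]), 2)
        assert mat[0, 1] == pytest.approx(0.3)

    def test_occupancy_weighted_means_recover_grand_mean(self, small_wfcs):
        w = small_wfcs[0]
        model = d.fit_states(small_wfcs, 3, n_restarts=3, seed=0)
        labels = model.labels[w.subject_id]
        grand = w.z.mean(axis=0)
        acc = np.zeros_like(grand)
        for s in range(1, 4):
            mat, visited = d.state_mean_fc(w, labels, s)
            if visited:
                acc += mat * (labels == s).mean()
        np.testing.assert_allclose(acc, grand, atol=1e-10)
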