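from itertools import combinations

import numpy as np
import pytest

from nmdp.sswespca import (
    SelectionParams,
    SparsePathwayPCA,
    edge_weights,
    evaluator_importance,
    fit_multi_pc,
    fit_pc,
    reweight_and_normalize,
    sparse_project,
    update_v,
)
from nmdp.synthetic import SimSpec, recovery_score, simulate_cohort
from nmdp.types_io import PathwayEdgeSet


class TestEdgeWeights:
    def test_pythagorean_pair(self):
        u = np.array([3.0, 4.0, 0.0])
        w = edge_weights(u, np.array([[0, 1]]))
        assert w[0] == 25.0

    def test_zero_vector(self):
        w = edge_weights(np.zeros(5), np.array([[0, 1], [2, 3]]))
        np.testing.assert_array_equal(w, [0.0, 0.0])

    def test_matches_elementwise_recomputation(self, rng):
        u = rng.normal(size=30)
        edges = np.array([(i, j) for i, j in zip(rng.integers(0, 30, 20),
                                                 rng.integers(0, 30, 20)) if i != j])
        w = edge_weights(u, edges)
        expected = [u[i] ** 2 + u[j] ** 2 for i, j in edges]
        np.testing.assert_allclose(w, expected)

    def test_sqrt_variant_preserves_ranking(self, rng):
        u = rng.normal(size=10)
        edges = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
        w = edge_weights(u, edges)
        ws = edge_weights(u, edges, sqrt=True)
        np.testing.assert_array_equal(np.argsort(w), np.argsort(ws))


class TestSparseProject:
    def test_omega_zero_is_deterministic_top_k(self):
        z = np.arange(6, dtype=float) + 1
        edges = np.array([[0, 1], [2, 3], [4, 5]])
        weights = np.array([5.0, 2.0, 1.0])
        for seed in range(5):
            out, sampled = sparse_project(z, edges, weights, k=1, omega=0.0,
                                          rng=np.random.default_rng(seed))
            np.testing.assert_array_equal(sampled, [0])
            np.testing.assert_array_equal(np.flatnonzero(out), [0, 1])

    def test_oversampled_support_within_enumerated_outcomes(self, rng):
        """omega=1, k=2, 6 edges: result must be one of the C(4,2) top-pool picks."""
        z = rng.normal(size=12)
        edges = np.asarray([[0, 1], [2, 3], [4, 5], [6, 7], [8, 9], [10, 11]])
        weights = np.array([6.0, 5, 4, 3, 2, 1])
        pool = [0, 1, 2, 3]  # ceil((1+1)*2) = 4 top edges
        allowed = {frozenset(c) for c in combinations(pool, 2)}
        seen = set()
        for seed in range(40):
            out, sampled = sparse_project(z, edges, weights, 2, 1.0,
                                          np.random.default_rng(seed))
            assert frozenset(sampled) in allowed
            verts = set(np.flatnonzero(out))
            assert verts == set(edges[sampled].ravel())
            seen.add(frozenset(sampled))
        assert len(seen) > 1  # the rng actually varies the draw

    def test_tie_break_prefers_lower_edge_index(self):
        z = np.ones(6)
        edges = np.array([[0, 1], [2, 3], [4, 5]])
        weights = np.array([1.0, 1.0, 1.0])
        out, sampled = sparse_project(z, edges, weights, 1, 0.0,
                                      np.random.default_rng(0))
        np.testing.assert_array_equal(sampled, [0])

    def test_k_larger_than_edges_rejected(self):
        with pytest.raises(ValueError):
            sparse_project(np.ones(4), np.array([[0, 1]]), np.array([1.0]), 2, 0.0,
                           np.random.default_rng(0))


class TestEvaluatorImportance:
    def test_separating_probe_gets_max_score(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = r.normal(size=(6, 60))
            X[2] = y * 4.0 + r.normal(0, 0.3, 60)  # planted separator
            t = evaluator_importance(X, y, seed=seed)
            hits += int(np.argmax(t) == 2 and t[2] == 2.0)
        assert hits >= 9

    def test_noise_probes_span_full_scale_without_mass_zeroing(self, rng):
        # on pure noise the scaled importances still span [0, 2] (min-max
        # contract) but only the argmin is zeroed, so reweighting cannot
        # collapse the support
        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(8, 50))
        t = evaluator_importance(X, y, seed=0)
        assert t.min() == 0.0 and t.max() == 2.0
        assert np.sum(t == 0.0) < 4

    def test_single_class_falls_back_to_ones(self, rng):
        with pytest.warns(UserWarning, match="single-class"):
            t = evaluator_importance(rng.normal(size=(4, 20)), np.zeros(20), seed=0)
        np.testing.assert_array_equal(t, np.ones(4))


class TestReweightUpdate:
    def test_all_ones_identity_up_to_normalization(self, rng):
        u = rng.normal(size=10)
        out = reweight_and_normalize(u, np.ones(10))
        np.testing.assert_allclose(out, u / np.linalg.norm(u))

    def test_zeroing_shrinks_support(self, rng):
        u = rng.normal(size=10)
        t = np.ones(10)
        t[:5] = 0.0
        out = reweight_and_normalize(u, t)
        assert np.flatnonzero(out).size == 5

    def test_unit_norm_contract(self, rng):
        for _ in range(10):
            u, t = rng.normal(size=20), rng.uniform(0, 2, 20)
            assert np.linalg.norm(reweight_and_normalize(u, t)) == pytest.approx(1.0)

    def test_update_v_identity(self):
        X = np.eye(4)
        v = update_v(X, np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(v, [1, 0, 0, 0])

    def test_update_v_rank_one(self, rng):
        u0 = rng.normal(size=6)
        u0 /= np.linalg.norm(u0)
        v0 = rng.normal(size=9)
        v0 /= np.linalg.norm(v0)
        X = np.outer(u0, v0)
        v = update_v(X, u0)
        assert abs(abs(v @ v0) - 1.0) < 1e-12


class TestFitPC:
    def test_convergence_honors_tolerance(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        y = truth.true_label
        params = SelectionParams(k=10, seed=0, tol=1e-4)
        pc = fit_pc(block.values, y, edges, params)
        assert pc.converged
        assert np.linalg.norm(pc.u) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(pc.v) == pytest.approx(1.0, abs=1e-9)

    def test_support_is_union_of_sampled_edge_vertices(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        pc = fit_pc(block.values, truth.true_label, edges, SelectionParams(k=10, seed=1))
        legal = set(edges[pc.sampled_edges[-1]].ravel())
        assert set(pc.support) <= legal
        assert len(pc.sampled_edges[-1]) == 10

    def test_seeded_runs_are_bit_identical(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        p = SelectionParams(k=10, seed=7)
        a = fit_pc(block.values, truth.true_label, edges, p)
        b = fit_pc(block.values, truth.true_label, edges, p)
        np.testing.assert_array_equal(a.u, b.u)
        assert a.iterations == b.iterations
        assert a.sampled_edges == b.sampled_edges

    def test_shuffled_labels_still_converge(self, default_cohort, rng):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        y = rng.permutation(truth.true_label)
        pc = fit_pc(block.values, y, edges, SelectionParams(k=10, seed=0))
        assert np.linalg.norm(pc.u) == pytest.approx(1.0, abs=1e-9)


class TestFitMultiPC:
    def test_single_pc_key_matrix_equals_support_rows(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        pcs, key = fit_multi_pc(block.values, truth.true_label, edges,
                                SelectionParams(k=10, seed=0, n_pcs=1))
        np.testing.assert_array_equal(key, block.values[pcs[0].support])

    def test_deflated_components_are_orthogonal(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        pcs, _ = fit_multi_pc(block.values, truth.true_label, edges,
                              SelectionParams(k=5, seed=0, n_pcs=2))
        assert len(pcs) == 2
        assert abs(pcs[0].u @ pcs[1].u) <= 1e-6

    def test_two_disjoint_components_recovered(self):
        # planted and decoy components are disjoint edge groups; with labels
        # aligned to the first and 2 PCs, the union support should cover the
        # planted genes well
        blocks, edge_set, ic50, truth = simulate_cohort(SimSpec(seed=11))
        block = blocks["expression"]
        edges = edge_set.align(block.probe_ids)
        pcs, _ = fit_multi_pc(block.values, truth.true_label, edges,
                              SelectionParams(k=10, seed=0, n_pcs=2))
        union = np.unique(np.concatenate([pc.support for pc in pcs]))
        sel = [block.probe_ids[i] for i in union]
        both = set(truth.signal_genes) | set(truth.decoy_genes)
        score = recovery_score(sel, both)
        assert score["jaccard"] >= 0.7


class TestEstimator:
    def test_sklearn_interface(self, default_cohort):
        blocks, edge_set, ic50, truth = default_cohort
        block = blocks["expression"]
        est = SparsePathwayPCA(edge_set=edge_set, probe_ids=block.probe_ids,
                               k=10, seed=0)
        Xs = block.values.T  # samples x probes
        out = est.fit(Xs, truth.true_label).transform(Xs)
        assert out.shape == (block.n_samples, est.support_.size)
        names = est.get_feature_names_out()
        assert len(names) == est.support_.size
        params = est.get_params()
        assert params["k"] == 10
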