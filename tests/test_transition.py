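import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transitnet import (
    TransitionConfig,
    align_networks,
    binarize_transition,
    keystone_taxa,
    run_transition_analysis,
    transition_matrix,
)

from conftest import net_from_adjacency, random_adjacency
from oracles import pinv_svd


class TestAlign:
    def test_identical_node_sets(self, rng):
        net = net_from_adjacency(random_adjacency(8, 0.4, rng))
        a, b, shared = align_networks(net, net)
        assert shared == net.taxon_ids
        np.testing.assert_array_equal(a, b)

    def test_intersection_policy(self, rng):
        n1 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n2 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n1.taxon_ids = ["a", "b", "c"]
        n2.taxon_ids = ["b", "c", "d"]
        _, _, shared = align_networks(n1, n2)
        assert shared == ["b", "c"]

    def test_union_policy_zero_pads(self, rng):
        n1 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n2 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n1.taxon_ids = ["a", "b", "c"]
        n2.taxon_ids = ["b", "c", "d"]
        a, b, shared = align_networks(n1, n2, policy="union")
        assert shared == ["a", "b", "c", "d"]
        d_pos = shared.index("d")
        assert a[d_pos, :].sum() == 0 and a[:, d_pos].sum() == 0
        a_pos = shared.index("a")
        assert b[a_pos, :].sum() == 0 and b[:, a_pos].sum() == 0

    def test_disjoint_sets_error(self, rng):
        n1 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n2 = net_from_adjacency(random_adjacency(3, 0.9, rng))
        n2.taxon_ids = ["x", "y", "z"]
        with pytest.raises(ValueError, match="disjoint"):
            align_networks(n1, n2)


class TestTransitionMatrix:
    def test_identity_when_equal_full_rank(self, rng):
        a = rng.standard_normal((6, 6))
        a = a @ a.T + 6 * np.eye(6)
        t = transition_matrix(a, a)
        np.testing.assert_allclose(t.matrix, np.eye(6), atol=1e-10)
        assert t.residual == pytest.approx(0.0, abs=1e-10)

    def test_identity_source_returns_target(self, rng):
        b = rng.standard_normal((5, 5))
        t = transition_matrix(np.eye(5), b)
        np.testing.assert_allclose(t.matrix, b, atol=1e-12)

    def test_rank_deficient_matches_svd_oracle(self, rng):
        # rank-3 source of dimension 6
        u = rng.standard_normal((6, 3))
        a = u @ u.T
        b = rng.standard_normal((6, 6))
        t = transition_matrix(a, b)
        rcond = 6 * np.finfo(float).eps
        expect = pinv_svd(a, rcond) @ b
        np.testing.assert_allclose(t.matrix, expect, atol=1e-10)
        # A @ T equals the oracle's projection of B onto range(A)
        np.testing.assert_allclose(a @ t.matrix, a @ expect, atol=1e-8)

    def test_literal_mode_uses_inverse_of_target(self, rng):
        a = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        b = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        lit = transition_matrix(a, b, mode="literal")
        np.testing.assert_allclose(lit.matrix, np.linalg.inv(b) @ a, atol=1e-8)
        # the literal product form satisfies B @ T = A, not A @ T = B
        np.testing.assert_allclose(b @ lit.matrix, a, atol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_consistent_mode_solves_product_relation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        a = rng.standard_normal((n, n)) + n * np.eye(n)  # full rank
        b = rng.standard_normal((n, n))
        t = transition_matrix(a, b)
        assert np.linalg.norm(a @ t.matrix - b, "fro") <= 1e-8
        assert t.residual <= 1e-8

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            transition_matrix(np.eye(3), np.eye(4))


class TestBinarize:
    def make_transition(self, m, ids=None):
        m = np.asarray(m, dtype=float)
        ids = ids or [f"t{i:02d}" for i in range(m.shape[0])]
        from transitnet.containers import TransitionNetwork

        return TransitionNetwork(ids, m, "A->B", "consistent", 1e-12)

    def test_density_one_gives_complete_graph(self, rng):
        t = self.make_transition(rng.standard_normal((6, 6)))
        view = binarize_transition(t, 1.0)
        assert view.n_edges == 15

    def test_diagonal_only_matrix_is_error(self):
        t = self.make_transition(np.diag([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="off-diagonal"):
            binarize_transition(t, 0.5)

    def test_edge_set_matches_sort_and_cut_oracle(self, rng):
        m = rng.standard_normal((12, 12))
        t = self.make_transition(m)
        view = binarize_transition(t, 0.2)
        strength = np.maximum(np.abs(m), np.abs(m.T))
        np.fill_diagonal(strength, 0)
        iu = np.triu_indices(12, 1)
        vals = strength[iu]
        n_keep = round(0.2 * len(vals))
        top = np.sort(vals)[::-1][:n_keep]
        got = strength[np.triu(view.adjacency, 1).astype(bool)]
        np.testing.assert_allclose(np.sort(got)[::-1], top)

    def test_nested_in_density(self, rng):
        m = rng.standard_normal((10, 10))
        lo = binarize_transition(self.make_transition(m), 0.1).adjacency
        hi = binarize_transition(self.make_transition(m), 0.4).adjacency
        assert ((lo == 1) & (hi == 0)).sum() == 0

    def test_tie_break_is_lexicographic_and_deterministic(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 1.0  # tied strengths
        t = self.make_transition(m, ids=["a", "b", "c", "d"])
        view = binarize_transition(t, 1 / 6)  # keep exactly one edge
        assert view.adjacency[0, 1] == 1 and view.adjacency[2, 3] == 0


class TestKeystones:
    def test_top_decile_count(self):
        fc = np.arange(50, dtype=float)
        ids = [f"t{i:02d}" for i in range(50)]
        rep = keystone_taxa(fc, ids, 0.10)
        assert rep.n_selected == 5
        assert rep.taxa == ["t49", "t48", "t47", "t46", "t45"]

    def test_boundary_ties_all_included(self):
        fc = np.array([5.0, 5.0, 5.0, 1.0, 0.0])
        rep = keystone_taxa(fc, list("abcde"), 0.2)  # ceil(0.2*5)=1 but 3 tied
        assert rep.n_selected == 3
        assert rep.taxa == ["a", "b", "c"]

    def test_all_equal_selects_everything(self):
        fc = np.full(7, 2.0)
        rep = keystone_taxa(fc, [f"t{i}" for i in range(7)], 0.10)
        assert rep.n_selected == 7

    def test_selected_dominate_unselected(self, rng):
        fc = rng.integers(0, 40, size=30).astype(float)
        ids = [f"t{i:02d}" for i in range(30)]
        rep = keystone_taxa(fc, ids, 0.10)
        unselected = [t for t in ids if t not in rep.taxa]
        floor = min(rep.flow_raw)
        assert all(fc[ids.index(t)] <= floor for t in unselected)

    def test_removing_unselected_node_keeps_set(self, rng):
        fc = np.array([9.0, 8.0, 7.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.0])
        ids = [f"t{i}" for i in range(10)]
        rep = keystone_taxa(fc, ids, 0.2)
        rep2 = keystone_taxa(fc[:-1], ids[:-1], 0.2)
        assert rep.taxa == rep2.taxa

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            keystone_taxa(np.array([]), [], 0.1)


class TestEndToEnd:
    def test_equal_networks_give_identity_like_result(self, rng):
        net = net_from_adjacency(random_adjacency(12, 0.4, rng))
        t_ab, t_ba, k_ab, k_ba = run_transition_analysis(net, net)
        assert t_ab.residual == pytest.approx(0.0, abs=1e-8)
        assert t_ba.residual == pytest.approx(0.0, abs=1e-8)
        assert k_ab.n_selected >= 2  # ceil(0.1 * 12) + possible ties

    def test_planted_bottleneck_hub_ranks_first(self, paired_small):
        """A hub bridging modules in one condition dominates the
        transition network's flow coefficient."""
        _, _, truth = paired_small
        t_ab, t_ba, k_ab, k_ba = run_transition_analysis(
            truth.network("ACT"), truth.network("SED")
        )
        for rep in (k_ab, k_ba):
            assert all(h in rep.taxa for h in truth.hubs)

    def test_keystone_report_count_matches_fraction(self, paired_small):
        _, _, truth = paired_small
        cfg = TransitionConfig(fraction=0.10)
        _, _, k_ab, _ = run_transition_analysis(
            truth.network("ACT"), truth.network("SED"), cfg
        )
        assert k_ab.n_selected >= int(np.ceil(0.10 * 30))

    def test_deterministic_given_config(self, paired_small):
        _, _, truth = paired_small
        a, b = truth.network("ACT"), truth.network("SED")
        r1 = run_transition_analysis(a, b)
        r2 = run_transition_analysis(a, b)
        np.testing.assert_array_equal(r1[0].matrix, r2[0].matrix)
        assert r1[2].taxa == r2[2].taxa
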