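import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transitnet import (
    clustering_coefficients,
    degree_assortativity,
    flow_coefficients,
    global_efficiency,
    topology_profile,
)

from conftest import net_from_adjacency, random_adjacency
from oracles import (
    assortativity_newman_sum,
    clustering_triple_loop,
    efficiency_floyd_warshall,
    flow_bruteforce,
)


def complete(n):
    return (np.ones((n, n)) - np.eye(n)).astype(np.int8)


def star(leaves):
    a = np.zeros((leaves + 1, leaves + 1), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def path(n):
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def cycle(n):
    a = path(n)
    a[0, n - 1] = a[n - 1, 0] = 1
    return a


class TestClosedForms:
    def test_complete_graph(self):
        a = complete(4)
        assert clustering_coefficients(a) == pytest.approx(np.ones(4))
        norm, raw = flow_coefficients(a)
        assert norm == pytest.approx(np.zeros(4))
        assert raw == pytest.approx(np.zeros(4))
        eff, cpl = global_efficiency(a)
        assert eff == pytest.approx(1.0)
        assert cpl == pytest.approx(1.0)

    def test_star_center(self):
        a = star(4)
        c = clustering_coefficients(a)
        norm, raw = flow_coefficients(a)
        assert c == pytest.approx(np.zeros(5))
        assert norm[0] == pytest.approx(1.0)
        assert raw[0] == pytest.approx(6.0)  # C(4,2) open pairs
        assert degree_assortativity(a) == pytest.approx(-1.0)

    def test_star_with_three_leaves_flow(self):
        norm, raw = flow_coefficients(star(3))
        assert norm[0] == pytest.approx(1.0)
        assert raw[0] == pytest.approx(3.0)

    def test_edgeless_graph(self):
        a = np.zeros((4, 4), dtype=np.int8)
        eff, cpl = global_efficiency(a)
        assert eff == 0.0
        assert np.isnan(cpl)
        with pytest.raises(ValueError, match="at least one edge"):
            degree_assortativity(a)

    def test_single_node(self):
        eff, cpl = global_efficiency(np.zeros((1, 1), dtype=np.int8))
        assert eff == 0.0 and np.isnan(cpl)

    def test_path_graph_efficiency(self):
        # pairs at distance 1,1,1,2,2,3 -> mean inverse = (3 + 1 + 1/3)/6
        eff, cpl = global_efficiency(path(4))
        assert eff == pytest.approx((3 + 2 * 0.5 + 1 / 3) / 6)
        assert eff == pytest.approx(0.72222, abs=1e-5)
        assert cpl == pytest.approx((3 * 1 + 2 * 2 + 3) / 6)

    def test_regular_cycle_assortativity_undefined(self):
        assert np.isnan(degree_assortativity(cycle(6)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        a = random_adjacency(n, rng.uniform(0.15, 0.6), rng)
        np.testing.assert_allclose(
            clustering_coefficients(a), clustering_triple_loop(a), atol=1e-12
        )
        norm, raw = flow_coefficients(a)
        o_norm, o_raw = flow_bruteforce(a)
        np.testing.assert_allclose(norm, o_norm, atol=1e-12)
        np.testing.assert_allclose(raw, o_raw, atol=1e-12)
        eff, cpl = global_efficiency(a)
        o_eff, o_cpl = efficiency_floyd_warshall(a)
        assert eff == pytest.approx(o_eff, abs=1e-12)
        assert (np.isnan(cpl) and np.isnan(o_cpl)) or cpl == pytest.approx(o_cpl)
        if a.sum() > 0:
            got = degree_assortativity(a)
            want = assortativity_newman_sum(a)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_assortativity_matches_networkx(self, rng):
        a = random_adjacency(25, 0.2, rng)
        g = nx.from_numpy_array(a)
        assert degree_assortativity(a) == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-10
        )


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_flow_plus_clustering_identity(self, seed):
        """Open and closed neighbor pairs partition: FC_norm + C = 1 (k >= 2)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        a = random_adjacency(n, rng.uniform(0.1, 0.7), rng)
        c = clustering_coefficients(a)
        norm, _ = flow_coefficients(a)
        k = a.sum(axis=1)
        mask = k >= 2
        np.testing.assert_allclose(norm[mask] + c[mask], 1.0, atol=1e-12)

    def test_efficiency_monotone_under_edge_addition(self, rng):
        a = random_adjacency(15, 0.15, rng)
        eff, _ = global_efficiency(a)
        zeros = np.argwhere(np.triu(a == 0, k=1))
        for i, j in zeros[rng.permutation(len(zeros))[:10]]:
            b = a.copy()
            b[i, j] = b[j, i] = 1
            eff2, _ = global_efficiency(b)
            assert eff2 >= eff - 1e-15

    def test_metrics_invariant_under_relabeling(self, rng):
        a = random_adjacency(18, 0.25, rng)
        perm = rng.permutation(18)
        b = a[np.ix_(perm, perm)]
        np.testing.assert_allclose(
            np.sort(clustering_coefficients(a)), np.sort(clustering_coefficients(b))
        )
        assert global_efficiency(a)[0] == pytest.approx(global_efficiency(b)[0])
        assert degree_assortativity(a) == pytest.approx(degree_assortativity(b))


class TestProfile:
    def test_profile_fields_equal_component_ops(self, rng):
        a = random_adjacency(20, 0.3, rng)
        net = net_from_adjacency(a)
        prof = topology_profile(net)
        np.testing.assert_array_equal(prof.degree, a.sum(axis=1))
        np.testing.assert_allclose(prof.clustering, clustering_coefficients(a))
        norm, raw = flow_coefficients(a)
        np.testing.assert_allclose(prof.flow_norm, norm)
        np.testing.assert_allclose(prof.flow_raw, raw)
        assert prof.efficiency_global == pytest.approx(global_efficiency(a)[0])
        assert prof.assortativity == pytest.approx(degree_assortativity(a))

    def test_profile_on_star(self):
        prof = topology_profile(net_from_adjacency(star(5)))
        assert prof.clustering[0] == 0.0
        assert prof.flow_norm[0] == 1.0
        assert prof.assortativity == pytest.approx(-1.0)

    def test_edgeless_profile_has_nan_assortativity(self):
        prof = topology_profile(net_from_adjacency(np.zeros((3, 3))))
        assert np.isnan(prof.assortativity)
        assert prof.efficiency_global == 0.0
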