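"""Graph metrics against closed-form and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from neuroculture.errors import ConfigurationError
from neuroculture.metrics import (
    clustering,
    degree_stats,
    global_efficiency,
    modularity,
    modularity_q,
    small_worldness,
    spatial_heatmap,
)


def ring_digraph(n):
    a = np.zeros((n, n), np.int8)
    for i in range(n):
        a[i, (i + 1) % n] = 1
    return a


class TestDegrees:
    def test_three_cycle(self):
        d = degree_stats(ring_digraph(3))
        assert np.array_equal(d.k_in, [1, 1, 1])
        assert np.array_equal(d.k_out, [1, 1, 1])

    def test_sums_match_edges(self):
        rng = np.random.default_rng(0)
        a = (rng.random((40, 40)) < 0.1).astype(np.int8)
        np.fill_diagonal(a, 0)
        d = degree_stats(a)
        assert d.k_in.sum() == d.k_out.sum() == a.sum()

    def test_gaussian_fit_recovers_moments(self):
        rng = np.random.default_rng(1)
        n = 4000
        target = rng.normal(50, 8, n).round().astype(int)
        # build a graph with prescribed in-degrees (sources chosen at random)
        rows, cols = [], []
        for j, k in enumerate(target):
            pres = rng.choice(np.delete(np.arange(n), j), size=k, replace=False)
            rows.extend(pres.tolist())
            cols.extend([j] * k)
        a = sparse.coo_matrix((np.ones(len(rows), np.int8), (rows, cols)),
                              shape=(n, n)).tocsr()
        d = degree_stats(a)
        assert d.mu_in == pytest.approx(50, abs=1.0)
        assert d.sigma_in == pytest.approx(8, abs=1.0)


class TestClustering:
    def test_bidirectional_triangle_is_one(self):
        a = np.ones((3, 3), np.int8)
        np.fill_diagonal(a, 0)
        assert clustering(a) == pytest.approx([1.0, 1.0, 1.0])

    def test_star_hub_zero(self):
        a = np.zeros((5, 5), np.int8)
        a[0, 1:] = 1
        assert clustering(a)[0] == 0.0

    def test_matches_exhaustive_triangle_enumeration(self):
        rng = np.random.default_rng(2)
        a = (rng.random((15, 15)) < 0.25).astype(float)
        np.fill_diagonal(a, 0)
        cc = clustering(a)
        # oracle: Fagiolo's directed CC by explicit triple enumeration
        n = len(a)
        s = a + a.T
        for i in range(n):
            tri = 0.0
            for j in range(n):
                for k in range(n):
                    if j != i and k != i and j != k:
                        tri += s[i, j] * s[j, k] * s[k, i]
            tri /= 2.0
            k_tot = a[i].sum() + a[:, i].sum()
            k_bi = (a[i] * a[:, i]).sum()
            denom = k_tot * (k_tot - 1) - 2 * k_bi
            expected = tri / denom if denom > 0 else 0.0
            assert cc[i] == pytest.approx(expected, abs=1e-12)

    def test_matches_networkx_fagiolo(self):
        rng = np.random.default_rng(3)
        a = (rng.random((20, 20)) < 0.2).astype(int)
        np.fill_diagonal(a, 0)
        g = nx.from_numpy_array(a, create_using=nx.DiGraph)
        nx_cc = nx.clustering(g)
        cc = clustering(a)
        for i in range(20):
            assert cc[i] == pytest.approx(nx_cc[i], abs=1e-12)


class TestModularity:
    def two_cliques(self):
        a = np.zeros((10, 10), np.int8)
        a[:5, :5] = 1
        a[5:, 5:] = 1
        np.fill_diagonal(a, 0)
        return a

    def test_two_cliques_q_half(self):
        a = self.two_cliques()
        labels = np.array([0] * 5 + [1] * 5)
        assert modularity_q(a, labels) == pytest.approx(0.5, abs=1e-12)
        res = modularity(a, seed=0)
        assert res.q == pytest.approx(0.5, abs=1e-9)
        assert res.n_communities == 2

    def test_complete_graph_single_community(self):
        a = np.ones((8, 8), np.int8)
        np.fill_diagonal(a, 0)
        res = modularity(a, seed=0)
        assert res.n_communities == 1
        assert res.q == pytest.approx(0.0, abs=1e-9)

    def test_q_reproducible_from_partition(self):
        rng = np.random.default_rng(4)
        a = (rng.random((60, 60)) < 0.08).astype(np.int8)
        np.fill_diagonal(a, 0)
        res = modularity(a, seed=1)
        assert modularity_q(a, res.partition) == pytest.approx(res.q, abs=1e-9)

    def test_matches_networkx_modularity(self):
        a = self.two_cliques()
        labels = np.array([0] * 5 + [1] * 5)
        g = nx.from_numpy_array((a + a.T).astype(float))
        q_nx = nx.community.modularity(g, [set(range(5)), set(range(5, 10))],
                                       weight="weight")
        assert modularity_q(a, labels) == pytest.approx(q_nx, abs=1e-12)

    def test_empty_graph_raises(self):
        with pytest.raises(ConfigurationError):
            modularity(np.zeros((4, 4)))


class TestEfficiency:
    def test_complete_digraph(self):
        a = np.ones((6, 6), np.int8)
        np.fill_diagonal(a, 0)
        assert global_efficiency(a).g_eff == pytest.approx(1.0)

    def test_three_node_bidirectional_path(self):
        a = np.zeros((3, 3), np.int8)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
        # ordered pairs: 4 at distance 1, 2 at distance 2 -> (4 + 1) / 6
        assert global_efficiency(a).g_eff == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_unreachable_pairs_contribute_zero(self):
        a = np.zeros((4, 4), np.int8)
        a[0, 1] = a[1, 0] = 1
        assert global_efficiency(a).g_eff == pytest.approx(2.0 / 12.0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_edge_deletion(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((12, 12)) < 0.3).astype(np.int8)
        np.fill_diagonal(a, 0)
        e_full = global_efficiency(a).g_eff
        edges = np.argwhere(a)
        if len(edges) == 0:
            return
        i, j = edges[rng.integers(len(edges))]
        a2 = a.copy()
        a2[i, j] = 0
        assert global_efficiency(a2).g_eff <= e_full + 1e-12


class TestSmallWorldness:
    def test_er_graph_near_one(self):
        rng = np.random.default_rng(5)
        a = (rng.random((120, 120)) < 0.08).astype(np.int8)
        np.fill_diagonal(a, 0)
        sigma = small_worldness(a, n_null=5, seed=0)
        assert 0.7 < sigma < 1.3

    def test_ring_lattice_with_shortcuts_above_one(self):
        g = nx.watts_strogatz_graph(120, 8, 0.05, seed=1)
        a = nx.to_numpy_array(g).astype(np.int8)
        sigma = small_worldness(a, n_null=5, seed=0)
        assert sigma > 1.5


class TestSpatialHeatmap:
    def test_flat_for_uniform_values(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(-0.9, 0.9, (400, 2))
        hm = spatial_heatmap(pos, np.full(400, 7.0), diameter=2.0)
        finite = hm.values[np.isfinite(hm.values)]
        assert np.allclose(finite, 7.0)
        assert hm.cell_size == pytest.approx(0.031)

    def test_cell_size_scales_with_diameter(self):
        pos = np.zeros((1, 2))
        hm = spatial_heatmap(pos, np.ones(1), diameter=8.0)
        assert hm.cell_size == pytest.approx(0.124)

    def test_planted_cluster_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(-1, 1, (500, 2))
        vals = np.where(np.hypot(pos[:, 0] - 0.3, pos[:, 1]) < 0.2, 10.0, 1.0)
        hm = spatial_heatmap(pos, vals, diameter=2.0)
        n = hm.values.shape[0]
        ix = np.clip(((pos[:, 0] + 1.0) / hm.cell_size).astype(int), 0, n - 1)
        iy = np.clip(((pos[:, 1] + 1.0) / hm.cell_size).astype(int), 0, n - 1)
        for cy, cx in [(5, 5), (20, 20), (n // 2, n // 2)]:
            m = (ix == cx) & (iy == cy)
            if m.any():
                assert hm.values[cy, cx] == pytest.approx(vals[m].mean())
            else:
                assert np.isnan(hm.values[cy, cx])
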