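"""Graph construction and metrics against hand values and brute-force oracles."""

import numpy as np
import networkx as nx
import pytest

from restfc import graph as g

from conftest import random_adjacency


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


# ---------------------------------------------------------------------- oracles


def brute_clustering(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        links = sum(
            adj[a, b] for x, a in enumerate(nbrs) for b in nbrs[x + 1 :]
        )
        out[i] = 2 * links / (k * (k - 1))
    return out


def brute_local_efficiency(adj):
    gg = nx.from_numpy_array(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = list(gg.neighbors(i))
        if len(nbrs) < 2:
            continue
        sub = gg.subgraph(nbrs)
        out[i] = nx.global_efficiency(sub)
    return out


def brute_harmonic_L(adj):
    gg = nx.from_numpy_array(adj)
    n = adj.shape[0]
    total = 0.0
    for a in range(n):
        lengths = nx.single_source_shortest_path_length(gg, a)
        for b, d in lengths.items():
            if b != a:
                total += 1.0 / d
    return n * (n - 1) / total


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def union_find_largest(adj):
    n = adj.shape[0]
    uf = UnionFind(n)
    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        uf.union(int(i), int(j))
    roots = [uf.find(k) for k in range(n)]
    return max(np.bincount(roots))


# ------------------------------------------------------------------- thresholds


class TestProportionalThreshold:
    def test_density_one_gives_complete_graph(self, rng):
        z = rng.standard_normal((6, 6))
        z = (z + z.T) / 2
        adj = g.proportional_threshold(z, 1.0)
        assert g.graph_n_edges(adj) == 15
        assert not adj.diagonal().any()

    def test_top_k_by_sorted_weights(self):
        # R=5: weights 1..10 assigned row-major; density 0.3 keeps ranks 10, 9, 8
        z = np.zeros((5, 5))
        iu, ju = np.triu_indices(5, 1)
        z[iu, ju] = np.arange(1, 11)
        z = z + z.T
        adj = g.proportional_threshold(z, 0.3)
        kept = set(zip(*np.nonzero(np.triu(adj, 1))))
        expected = {tuple(sorted((int(iu[k]), int(ju[k])))) for k in (7, 8, 9)}
        assert kept == expected

    def test_exact_edge_count_at_10_percent_of_116(self, rng):
        z = rng.standard_normal((116, 116))
        z = (z + z.T) / 2
        adj = g.proportional_threshold(z, 0.1)
        assert g.graph_n_edges(adj) == 667  # round(0.1 * 6670)

    def test_ties_break_by_ascending_pair_order(self):
        z = np.ones((4, 4)) - np.eye(4)
        adj = g.proportional_threshold(z, 2 / 6)
        kept = sorted(zip(*np.nonzero(np.triu(adj, 1))))
        assert kept == [(0, 1), (0, 2)]

    def test_invalid_density_raises(self, rng):
        z = np.zeros((4, 4))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                g.proportional_threshold(z, bad)


# --------------------------------------------------------------------- metrics


class TestMetrics:
    def test_triangle_and_star_clustering(self):
        k3 = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert np.allclose(g.nodal_clustering(k3), 1.0)
        star = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert np.allclose(g.nodal_clustering(star), 0.0)

    def test_local_efficiency_examples(self):
        k5 = ~np.eye(5, dtype=bool)
        assert np.allclose(g.nodal_local_efficiency(k5), 1.0)
        path = adj_from_edges(3, [(0, 1), (1, 2)])
        assert g.nodal_local_efficiency(path)[1] == 0.0

    def test_path_length_hand_values(self):
        k4 = ~np.eye(4, dtype=bool)
        assert g.characteristic_path_length(k4) == pytest.approx(1.0)
        two_k2 = adj_from_edges(4, [(0, 1), (2, 3)])
        assert g.characteristic_path_length(two_k2) == pytest.approx(3.0)
        path3 = adj_from_edges(3, [(0, 1), (1, 2)])
        assert g.characteristic_path_length(path3) == pytest.approx(1.2)

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            g.characteristic_path_length(np.zeros((4, 4), dtype=bool))

    def test_component_sizes(self, rng):
        path = adj_from_edges(6, [(k, k + 1) for k in range(5)])
        assert g.largest_component_size(path) == 6
        assert g.largest_component_size(np.zeros((5, 5), dtype=bool)) == 1
        adj = random_adjacency(20, 0.1, rng)
        assert g.largest_component_size(adj) == union_find_largest(adj)

    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_match_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        adj = random_adjacency(n, float(rng.uniform(0.2, 0.7)), rng)
        assert np.allclose(g.nodal_clustering(adj), brute_clustering(adj), atol=1e-12)
        assert np.allclose(
            g.nodal_local_efficiency(adj), brute_local_efficiency(adj), atol=1e-10
        )
        if g.graph_n_edges(adj) > 0:
            assert g.characteristic_path_length(adj) == pytest.approx(
                brute_harmonic_L(adj), abs=1e-10
            )


# --------------------------------------------------------------------- rewiring


class TestRewiring:
    def test_degree_sequence_and_simplicity_preserved(self, rng):
        adj = random_adjacency(20, 0.3, rng)
        null, n_swaps = g.double_edge_swap(adj, 10 * g.graph_n_edges(adj), rng)
        assert np.array_equal(null.sum(0), adj.sum(0))
        assert not null.diagonal().any()
        assert np.array_equal(null, null.T)
        assert g.graph_n_edges(null) == g.graph_n_edges(adj)
        assert n_swaps > 0
        assert (null != adj).any()

    def test_four_cycle_nulls_are_four_cycles(self, rng):
        c4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        for null in g.maslov_sneppen_ensemble(c4, g.NullEnsembleSpec(10, 10), rng):
            assert np.array_equal(null.sum(0), np.full(4, 2))
            assert g.largest_component_size(null) == 4  # a single 4-cycle

    def test_too_small_graph_returns_copy(self, rng, caplog):
        single = adj_from_edges(3, [(0, 1)])
        null, n_swaps = g.double_edge_swap(single, 5, rng)
        assert n_swaps == 0
        assert np.array_equal(null, single)


class TestSmallWorldness:
    def test_complete_graph_is_fixed_point(self, rng):
        k8 = ~np.eye(8, dtype=bool)
        sw = g.small_worldness(k8, g.NullEnsembleSpec(5, 5), rng)
        assert sw.clustering == pytest.approx(1.0)
        assert sw.path_length == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(1.0)

    def test_triangle_free_null_flags_sigma_nan(self, rng):
        # star graph: nulls keep the star degree sequence -> no triangles
        star = adj_from_edges(5, [(0, k) for k in range(1, 5)])
        sw = g.small_worldness(star, g.NullEnsembleSpec(3, 5), rng)
        assert np.isnan(sw.sigma)


class TestDensityGrid:
    def test_default_grid_has_19_levels(self):
        grid = g.default_density_grid()
        assert len(grid) == 19
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(0.95)

    def test_edge_counts_increase_and_metrics_converge(self, rng):
        z = rng.standard_normal((24, 24))
        z = (z + z.T) / 2
        res = g.run_density_grid(
            {"s0": z}, grid=[0.2, 0.5, 1.0], spec=g.NullEnsembleSpec(3, 5), seed=1
        )
        gdf = res.global_.sort_values("density")
        counts = gdf["n_edges"].to_numpy()
        assert (np.diff(counts) > 0).all()
        # at density 1 the graph is complete: normalized metrics equal 1
        full = gdf[gdf["density"] == 1.0].iloc[0]
        assert full["C_norm"] == pytest.approx(1.0)
        assert full["L_norm"] == pytest.approx(1.0)
        assert full["sigma"] == pytest.approx(1.0)

    def test_deterministic_under_fixed_seed(self, rng):
        z = rng.standard_normal((12, 12))
        z = (z + z.T) / 2
        a = g.run_density_grid({"s": z}, grid=[0.2, 0.4], spec=g.NullEnsembleSpec(4, 5), seed=9)
        b = g.run_density_grid({"s": z}, grid=[0.2, 0.4], spec=g.NullEnsembleSpec(4, 5), seed=9)
        assert a.global_.equals(b.global_)
        assert a.nodal.equals(b.nodal)
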