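"""Graph statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    brute_path_length,
    enumerate_betweenness,
    fw_distances,
    random_connected_graph,
)

from fconn.errors import ValidationError
from fconn.graph_metrics import (
    auc,
    betweenness,
    clustering,
    cost_efficiency,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    path_length,
    rewire_preserving_degree,
    shortest_paths,
    small_world_indices,
)
from fconn.network import BinaryGraph, SparsityGrid
from fconn.synth import generate_small_world_graph


def adjacency(edges, n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


K5 = adjacency([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)
STAR4 = adjacency([(0, 1), (0, 2), (0, 3), (0, 4)], 5)  # center 0, 4 leaves
PATH3 = adjacency([(0, 1), (1, 2)], 3)
TRIANGLE_PENDANT = adjacency([(0, 1), (0, 2), (1, 2), (0, 3)], 4)


class TestClustering:
    def test_complete_graph_fully_clustered(self):
        c, cp = clustering(K5)
        assert np.allclose(c, 1.0) and cp == 1.0

    def test_star_has_no_triangles(self):
        c, cp = clustering(STAR4)
        assert np.allclose(c, 0.0) and cp == 0.0

    def test_triangle_with_pendant_hand_count(self):
        c, cp = clustering(TRIANGLE_PENDANT)
        assert np.allclose(c, [1 / 3, 1, 1, 0])
        assert cp == pytest.approx(7 / 12)


class TestDistancesAndPathLength:
    def test_path_graph_distance(self):
        d = shortest_paths(PATH3)
        assert d[0, 2] == 2

    def test_disconnected_components_are_infinite(self):
        two_triangles = adjacency(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6
        )
        d = shortest_paths(two_triangles)
        assert np.isinf(d[0, 3])

    def test_path_graph_nodal_lengths(self):
        li, lp, _ = path_length(PATH3)
        assert np.allclose(li, [1.5, 1.0, 1.5])
        assert lp == pytest.approx(4 / 3)

    def test_complete_graph_unit_length(self):
        _, lp, _ = path_length(adjacency([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 4))
        assert lp == 1.0

    def test_isolated_node_excluded_with_warning(self):
        a = adjacency([(0, 1)], 3)
        with pytest.warns(UserWarning, match="excluded"):
            li, lp, n_excluded = path_length(a)
        assert np.isnan(li[2])
        assert lp == 1.0
        assert n_excluded == 4  # ordered pairs involving node 2


class TestEfficiencies:
    def test_complete_graph_unit_global_efficiency(self):
        assert global_efficiency(K5) == 1.0

    def test_path_graph_hand_value(self):
        assert global_efficiency(PATH3) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_edgeless_graph_zero(self):
        assert global_efficiency(np.zeros((4, 4), dtype=np.uint8)) == 0.0

    def test_star_center_and_leaf_nodal_efficiency(self):
        e = nodal_efficiency(STAR4)
        assert e[0] == 1.0
        assert e[1] == pytest.approx((1 + 0.5 + 0.5 + 0.5) / 4)

    def test_mean_nodal_equals_global(self, rng):
        for _ in range(10):
            a = random_connected_graph(8, rng)
            assert nodal_efficiency(a).mean() == pytest.approx(
                global_efficiency(a), abs=1e-12
            )

    def test_complete_graph_unit_local_efficiency(self):
        assert local_efficiency(K5) == 1.0

    def test_star_zero_local_efficiency(self):
        # each leaf has one neighbor; the center's neighbors are edgeless
        assert local_efficiency(STAR4) == 0.0


class TestBetweenness:
    def test_path_graph_middle_carries_all(self):
        assert np.allclose(betweenness(PATH3), [0, 1, 0])

    def test_star_center_routes_all_leaf_pairs(self):
        bc = betweenness(STAR4)
        assert bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.allclose(bc[1:], 0.0)

    def test_matches_literal_path_enumeration(self, rng):
        for _ in range(10):
            a = random_connected_graph(6, rng)
            assert np.allclose(betweenness(a), enumerate_betweenness(a), atol=1e-10)


class TestOracleEquivalence:
    """Every statistic equals its independent brute-force oracle on small graphs."""

    @pytest.mark.parametrize("trial", range(25))
    def test_all_statistics_match(self, trial):
        rng = np.random.default_rng(1000 + trial)
        a = random_connected_graph(8, rng)
        assert np.allclose(shortest_paths(a), fw_distances(a))
        assert np.allclose(clustering(a)[0], brute_clustering(a), atol=1e-12)
        li, lp, _ = path_length(a)
        oli, olp = brute_path_length(a)
        assert np.allclose(li, oli, equal_nan=True)
        assert lp == pytest.approx(olp)
        assert global_efficiency(a) == pytest.approx(brute_global_efficiency(a))
        assert np.allclose(nodal_efficiency(a), brute_nodal_efficiency(a))
        assert local_efficiency(a) == pytest.approx(brute_local_efficiency(a))
        assert np.allclose(betweenness(a), brute_betweenness(a), atol=1e-10)


class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        for seed in range(20):
            a = (rng.random((15, 15)) < 0.3)
            a = np.triu(a, 1)
            a = (a | a.T).astype(np.uint8)
            if a.sum() < 4:
                continue
            out = rewire_preserving_degree(a, seed=seed)
            assert np.array_equal(out.adjacency.sum(axis=1), a.sum(axis=1))

    def test_randomization_destroys_clustering(self):
        graph = generate_small_world_graph(90, 10, 0.05, seed=4)
        _, cp = clustering(graph.adjacency)
        nulls = [
            rewire_preserving_degree(graph.adjacency, seed=s) for s in range(10)
        ]
        null_cp = np.mean([clustering(g.adjacency)[1] for g in nulls])
        assert null_cp < cp

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValidationError):
            rewire_preserving_degree(adjacency([(0, 1)], 3), seed=0)


class TestSmallWorldIndices:
    def test_self_null_gives_unity(self):
        # zero swaps leave the graph unchanged: its own null population
        graph = generate_small_world_graph(30, 4, 0.1, seed=2)
        sw = small_world_indices(graph.adjacency, n_random=3, seed=0, swap_factor=0)
        assert sw.gamma == pytest.approx(1.0)
        assert sw.lam == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(1.0)

    def test_lattice_like_graph_is_small_world(self):
        graph = generate_small_world_graph(90, 10, 0.1, seed=1)
        sw = small_world_indices(graph.adjacency, n_random=20, seed=0)
        assert sw.sigma > 1.1

    def test_seeded_runs_are_reproducible(self):
        graph = generate_small_world_graph(40, 6, 0.2, seed=9)
        a = small_world_indices(graph.adjacency, n_random=5, seed=11)
        b = small_world_indices(graph.adjacency, n_random=5, seed=11)
        assert (a.gamma, a.lam, a.sigma) == (b.gamma, b.lam, b.sigma)


class TestAuc:
    def grid(self):
        return SparsityGrid.from_range(0.11, 0.44, 0.01)

    def test_constant_curve(self):
        grid = self.grid()
        assert auc(np.full(len(grid), 2.0), grid) == pytest.approx(0.66)

    def test_identity_curve_closed_form(self):
        grid = self.grid()
        assert auc(grid.values, grid) == pytest.approx(0.33 * (0.11 + 0.44) / 2)

    def test_single_interval(self):
        grid = SparsityGrid(values=np.array([0.1, 0.2]), step=0.1)
        assert auc(np.array([1.0, 3.0]), grid) == pytest.approx(0.2)

    def test_linearity(self, rng):
        grid = self.grid()
        y = rng.normal(size=len(grid))
        z = rng.normal(size=len(grid))
        assert auc(2.5 * y - 1.5 * z, grid) == pytest.approx(
            2.5 * auc(y, grid) - 1.5 * auc(z, grid)
        )


class TestCostEfficiency:
    def grid(self):
        return SparsityGrid.from_range(0.11, 0.44, 0.01)

    def test_complete_at_all_costs_peaks_at_cheapest(self):
        grid = self.grid()
        res = cost_efficiency(np.ones(len(grid)), grid)
        assert res.argmax_sparsity == pytest.approx(0.11)

    def test_zero_difference_flags_tie(self):
        grid = self.grid()
        res = cost_efficiency(grid.values.copy(), grid)
        assert res.argmax_sparsity == pytest.approx(0.11)
        assert res.tie

    def test_concave_curve_matches_direct_scan(self, rng):
        grid = self.grid()
        eglo = 1 - (grid.values - 0.3) ** 2 + 0.001 * rng.normal(size=len(grid))
        res = cost_efficiency(eglo, grid)
        diff = eglo - grid.values
        assert res.argmax_sparsity == pytest.approx(grid.values[np.argmax(diff)])
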