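"""Synthetic-data generator: ground truth must be recoverable downstream."""

import numpy as np
import pytest

from fconn.errors import ValidationError
from fconn.graph_metrics import clustering
from fconn.network import correlation_matrix
from fconn.prep import compute_fd, scrub
from fconn.synth import (
    GroundTruthSpec,
    degrade_nodes,
    generate_behavioral_scores,
    generate_dataset,
    generate_motion_trace,
    generate_small_world_graph,
    graph_to_timeseries,
    population_correlation,
)


class TestSmallWorldGraph:
    def test_ring_lattice_clustering_closed_form(self):
        # C = 3(k-2) / (4(k-1)) for the beta = 0 ring lattice
        graph = generate_small_world_graph(10, 4, 0.0)
        c, cp = clustering(graph.adjacency)
        assert cp == pytest.approx(3 * (4 - 2) / (4 * (4 - 1)))
        assert np.allclose(c, 0.5)

    def test_lattice_edge_count_and_degrees(self):
        graph = generate_small_world_graph(10, 4, 0.0)
        assert graph.n_edges == 20
        assert set(graph.degrees()) == {4}

    def test_edge_count_invariant_under_rewiring(self):
        for seed in range(10):
            graph = generate_small_world_graph(50, 6, 0.3, seed=seed)
            assert graph.n_edges == 150

    def test_odd_k_rejected(self):
        with pytest.raises(ValidationError):
            generate_small_world_graph(10, 3, 0.1)

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValidationError):
            generate_small_world_graph(6, 6, 0.1)


class TestGraphToTimeseries:
    def test_zero_edge_weight_gives_independent_channels(self):
        graph = generate_small_world_graph(6, 2, 0.0)
        ts = graph_to_timeseries(graph, 10_000, edge_weight=0.0, seed=5)
        r = np.corrcoef(ts.data)
        off = r[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_two_node_correlation_matches_population(self):
        adj = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        from fconn.network import BinaryGraph

        graph = BinaryGraph(adjacency=adj)
        pop_r = population_correlation(graph, 0.5)[0, 1]
        ts = graph_to_timeseries(graph, 10_000, edge_weight=0.5, seed=8)
        sample_r = np.corrcoef(ts.data)[0, 1]
        assert sample_r == pytest.approx(pop_r, abs=0.03)

    def test_seeds_change_sample_not_population(self):
        graph = generate_small_world_graph(8, 4, 0.0)
        a = graph_to_timeseries(graph, 200, seed=1)
        b = graph_to_timeseries(graph, 200, seed=2)
        assert not np.allclose(a.data, b.data)
        assert a.data.shape == b.data.shape

    def test_adjacent_pairs_more_correlated(self):
        graph = generate_small_world_graph(20, 4, 0.0)
        ts = graph_to_timeseries(graph, 5000, edge_weight=0.3, seed=3)
        r = np.corrcoef(ts.data)
        adj = graph.adjacency.astype(bool)
        off = ~np.eye(20, dtype=bool)
        assert r[adj].mean() > r[off & ~adj].mean() + 0.2


class TestDegradation:
    def test_affected_degree_drops_and_edge_count_conserved(self, rng):
        graph = generate_small_world_graph(30, 6, 0.1, seed=0)
        out = degrade_nodes(graph, (4,), 0.5, rng)
        assert out.n_edges == graph.n_edges
        assert out.degrees()[4] == graph.degrees()[4] - round(
            0.5 * graph.degrees()[4]
        )

    def test_lower_degree_in_expectation_across_replicates(self):
        # the planted group-B effect the inference stage must recover
        diffs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            graph = generate_small_world_graph(30, 6, 0.1, seed=seed)
            degraded = degrade_nodes(graph, (4,), 0.5, rng)
            diffs.append(graph.degrees()[4] - degraded.degrees()[4])
        assert np.mean(diffs) > 1.0


class TestMotionTrace:
    def test_spikes_scrubbed_exactly(self):
        motion = generate_motion_trace(97, (10, 50), 1.0, seed=0)
        fd = compute_fd(motion)
        assert set(np.flatnonzero(fd > 0.3)) == {10, 50}

    def test_no_spikes_no_scrubbing(self):
        motion = generate_motion_trace(97, (), seed=1)
        assert (compute_fd(motion) <= 0.3).all()

    def test_zero_drift_zero_fd(self):
        motion = generate_motion_trace(50, (), seed=2, drift_step=0.0)
        assert np.allclose(compute_fd(motion), 0.0)

    def test_subthreshold_spike_survives(self):
        motion = generate_motion_trace(60, (5,), 0.2, seed=3, drift_step=0.0)
        assert (compute_fd(motion) <= 0.3).all()

    def test_spike_at_frame_zero_rejected(self):
        with pytest.raises(ValidationError, match="frame 0"):
            generate_motion_trace(50, (0,), 1.0)

    def test_scrub_roundtrip_through_prep(self):
        from fconn.prep import SubjectTimeSeries

        motion = generate_motion_trace(97, (10, 50), 1.0, seed=4)
        ts = SubjectTimeSeries(
            data=np.random.default_rng(0).normal(size=(5, 97)), tr_seconds=3.0
        )
        out = scrub(ts, compute_fd(motion), 0.3)
        assert out.n_frames == 95
        assert not out.frame_mask[10] and not out.frame_mask[50]


class TestBehavioralScores:
    def test_noiseless_scores_correlate_perfectly(self):
        values = np.random.default_rng(0).normal(size=18)
        scores = generate_behavioral_scores(values, slope=1.0, noise_sd=0.0)
        assert np.corrcoef(values, scores)[0, 1] == pytest.approx(1.0)

    def test_zero_slope_gives_null_correlation(self):
        # |r| at n=18 has sd ~ 0.24 under the null; check across seeds
        rs = []
        for seed in range(10):
            values = np.random.default_rng(seed).normal(size=18)
            scores = generate_behavioral_scores(
                values, slope=0.0, noise_sd=1.0, seed=seed + 100
            )
            rs.append(abs(np.corrcoef(values, scores)[0, 1]))
        assert np.median(rs) < 0.5
        assert sum(r < 0.5 for r in rs) >= 8

    def test_target_population_correlation_recovered(self):
        # noise chosen for population r = 0.6; mean sample r over many
        # replicates should concentrate near it
        target = 0.6
        rs = []
        rng = np.random.default_rng(10)
        for _ in range(500):
            values = rng.standard_normal(18)
            noise_sd = np.sqrt(1.0 / target**2 - 1.0)
            scores = generate_behavioral_scores(
                values, slope=1.0, noise_sd=noise_sd, seed=rng
            )
            rs.append(np.corrcoef(values, scores)[0, 1])
        # E[r] is slightly below rho at n=18 (finite-sample bias ~ -rho(1-rho^2)/2n)
        assert np.mean(rs) == pytest.approx(target, abs=0.05)


class TestDatasetGeneration:
    def test_bit_reproducible_for_same_seed(self):
        spec = GroundTruthSpec(
            n_nodes=20, n_subjects_per_group=3, n_timepoints=40, k=4, seed=7,
            affected_nodes=(2,),
        )
        a = generate_dataset(spec)
        b = generate_dataset(spec)
        for ts_a, ts_b in zip(a.timeseries, b.timeseries):
            assert np.array_equal(ts_a.data, ts_b.data)
        for m_a, m_b in zip(a.motions, b.motions):
            assert np.array_equal(m_a.params, m_b.params)
        assert a.manifest.equals(b.manifest)

    def test_counts_and_group_labels(self):
        spec = GroundTruthSpec(
            n_nodes=20, n_subjects_per_group=4, n_timepoints=40, k=4, seed=1,
            affected_nodes=(2,),
        )
        ds = generate_dataset(spec)
        assert len(ds.timeseries) == 8
        assert (ds.manifest["group"] == "A").sum() == 4
        assert (ds.manifest["group"] == "B").sum() == 4

    def test_group_b_degraded_at_affected_nodes(self):
        spec = GroundTruthSpec(
            n_nodes=30, n_subjects_per_group=10, n_timepoints=40, k=6,
            affected_nodes=(5,), degradation_fraction=0.5, seed=3,
        )
        ds = generate_dataset(spec)
        deg_a = np.mean(
            [ds.true_graphs[i].degrees()[5] for i in ds.group_indices("A")]
        )
        deg_b = np.mean(
            [ds.true_graphs[i].degrees()[5] for i in ds.group_indices("B")]
        )
        assert deg_b < deg_a - 1.5

    def test_network_recoverable_from_timeseries(self):
        # binarizing at the generator's true sparsity recovers most edges
        spec = GroundTruthSpec(
            n_nodes=30, n_subjects_per_group=1, n_timepoints=600, k=6,
            affected_nodes=(), edge_weight=0.4, seed=11,
        )
        ds = generate_dataset(spec)
        from fconn.network import binarize_at_sparsity

        truth = ds.true_graphs[0]
        cm = correlation_matrix(ds.timeseries[0])
        recovered = binarize_at_sparsity(cm, truth.sparsity)
        overlap = np.sum(
            (recovered.adjacency == 1) & (truth.adjacency == 1)
        ) / truth.adjacency.sum()
        assert overlap >= 0.95
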