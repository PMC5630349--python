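"""Synthetic two-group connectome datasets with known ground truth.

Emulates the design of a two-group resting-state study — two groups of
18 subjects, 90 ROIs observed for 97 frames at TR = 3 s — so that every
downstream stage (preprocessing, network construction, graph metrics,
group inference, behavioral correlation) has a recoverable target:

* each subject's "true" functional network is a Watts–Strogatz
  small-world graph; in group B a chosen set of nodes is degraded by
  reallocating a fraction of their edges elsewhere in the graph
  (global edge count preserved, affected-node degree reduced);
* ROI time series are drawn from a zero-mean multivariate Gaussian
  whose covariance is ``I + w * A`` (eigenvalue-clipped to stay
  positive definite), so adjacent node pairs are more correlated than
  non-adjacent pairs and top-|z| binarization recovers the graph;
* motion traces are low-amplitude random-walk drift plus persistent
  step displacements at chosen spike frames, so FD-based scrubbing has
  an exact frame-level ground truth;
* behavioral scores are a linear function of a reference nodal metric
  plus Gaussian noise, so brain–behavior correlation recovery can be
  scored against a known population correlation.

All randomness flows from a single master seed through a documented
`numpy.random.SeedSequence` splitting scheme (see
:func:`generate_dataset`), making every stage independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from fconn.errors import ComputationError, ValidationError
from fconn.network import BinaryGraph
from fconn.prep import MotionTrace, SubjectTimeSeries

__all__ = [
    "GroundTruthSpec",
    "SyntheticDataset",
    "generate_small_world_graph",
    "degrade_nodes",
    "graph_to_timeseries",
    "generate_motion_trace",
    "generate_behavioral_scores",
    "generate_dataset",
]

#: Behavioral score columns: total plus the three subscales.
SCORE_COLUMNS = ("total", "attention", "motor", "nonplanning")
_SCORE_INTERCEPTS = {"total": 70.0, "attention": 18.0, "motor": 24.0,
                     "nonplanning": 28.0}


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of the generating model (defaults = the study design).

    ``affected_nodes`` are 0-based node indices degraded in group B;
    the defaults sit in default-mode / visual-like territory of the
    90-region parcellation (anterior cingulate, posterior cingulate,
    lingual, precuneus). ``behavior_node`` (default: the first affected
    node) supplies the nodal value that drives the behavioral scores.
    """

    n_nodes: int = 90
    n_subjects_per_group: int = 18
    n_timepoints: int = 97
    tr_seconds: float = 3.0
    k: int = 10
    beta: float = 0.1
    affected_nodes: tuple[int, ...] | None = None
    degradation_fraction: float = 0.5
    edge_weight: float = 0.25
    noise_sd: float = 1.0
    spike_probability: float = 0.03
    spike_amplitude_mm: float = 0.6
    behavior_slope: float = 1.0
    behavior_noise_sd: float = 3.0
    behavior_node: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValidationError("n_nodes must be >= 4")
        if self.affected_nodes is None:
            # 90-node default targets; otherwise four spread-out nodes
            if self.n_nodes >= 90:
                nodes: tuple[int, ...] = (31, 34, 46, 66)
            else:
                nodes = tuple(
                    sorted({self.n_nodes // 8, self.n_nodes // 3,
                            self.n_nodes // 2, 3 * self.n_nodes // 4})
                )
            object.__setattr__(self, "affected_nodes", nodes)
        else:
            object.__setattr__(self, "affected_nodes",
                               tuple(self.affected_nodes))
        if not 0 <= self.beta <= 1:
            raise ValidationError("beta must be in [0, 1]")
        if not 0 <= self.degradation_fraction <= 1:
            raise ValidationError("degradation_fraction must be in [0, 1]")
        if any(not 0 <= a < self.n_nodes for a in self.affected_nodes):
            raise ValidationError("affected_nodes must lie in [0, n_nodes)")
        if self.k % 2 or not 2 <= self.k < self.n_nodes:
            raise ValidationError("k must be even with 2 <= k < n_nodes")
        if self.behavior_noise_sd < 0 or self.noise_sd <= 0:
            raise ValidationError("noise SDs must be non-negative")

    @property
    def reference_node(self) -> int:
        if self.behavior_node is not None:
            return self.behavior_node
        if self.affected_nodes:
            return self.affected_nodes[0]
        return 0


@dataclass(frozen=True)
class SyntheticDataset:
    """One realized study: per-subject series, motion, behavior, truth."""

    spec: GroundTruthSpec
    timeseries: tuple[SubjectTimeSeries, ...]
    motions: tuple[MotionTrace, ...]
    true_graphs: tuple[BinaryGraph, ...]
    manifest: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        n = 2 * self.spec.n_subjects_per_group
        if not (len(self.timeseries) == len(self.motions)
                == len(self.true_graphs) == len(self.manifest) == n):
            raise ValidationError("dataset components disagree on subject count")
        if set(self.manifest["group"]) - {"A", "B"}:
            raise ValidationError("group labels must be 'A' or 'B'")

    @property
    def subject_ids(self) -> list[str]:
        return self.manifest["subject_id"].tolist()

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.manifest["group"] == group).to_numpy())


def generate_small_world_graph(
    n_nodes: int, k: int, beta: float, seed: int = 0
) -> BinaryGraph:
    """Watts–Strogatz ring-lattice graph with probabilistic rewiring.

    Every node starts with ``k`` lattice neighbors; each lattice edge is
    rewired with probability ``beta`` (endpoint moved, never deleted),
    so the edge count is ``n_nodes * k / 2`` for every beta and at
    beta = 0 all degrees equal ``k``.
    """
    if k % 2:
        raise ValidationError(f"k must be even; got {k}")
    if not 2 <= k < n_nodes:
        raise ValidationError(f"need 2 <= k < n_nodes; got k={k}, n={n_nodes}")
    if not 0 <= beta <= 1:
        raise ValidationError("beta must be in [0, 1]")
    g = nx.watts_strogatz_graph(n_nodes, k, beta, seed=int(seed))
    return BinaryGraph(adjacency=nx.to_numpy_array(g, dtype=np.uint8))


def degrade_nodes(
    graph: BinaryGraph,
    affected_nodes: tuple[int, ...],
    fraction: float,
    rng: np.random.Generator,
) -> BinaryGraph:
    """Disrupt the topology of selected nodes, preserving total edge count.

    For each affected node, ``round(fraction * degree)`` of its incident
    edges are deleted and the same number of edges are added between
    uniformly random currently-unconnected pairs that do not involve the
    node. The affected node's degree (and hence its nodal efficiency)
    drops in expectation while the graph's global cost is unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must be in [0, 1]")
    adj = graph.adjacency.astype(bool).copy()
    n = adj.shape[0]
    for a in affected_nodes:
        nbrs = np.flatnonzero(adj[a])
        n_remove = int(round(fraction * nbrs.size))
        if n_remove == 0:
            continue
        removed = rng.choice(nbrs, size=n_remove, replace=False)
        for b in removed:
            adj[a, b] = adj[b, a] = False
        for _ in range(n_remove):
            for _attempt in range(10000):
                c, d = rng.integers(0, n, size=2)
                if c == d or c == a or d == a or adj[c, d]:
                    continue
                adj[c, d] = adj[d, c] = True
                break
            else:
                raise ComputationError(
                    "could not place a replacement edge (graph too dense?)"
                )
    return BinaryGraph(adjacency=adj.astype(np.uint8),
                       node_labels=graph.node_labels)


def graph_to_timeseries(
    graph: BinaryGraph,
    n_timepoints: int,
    edge_weight: float = 0.25,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 3.0,
    subject_id: str | None = None,
) -> SubjectTimeSeries:
    """Gaussian ROI series whose population covariance encodes the graph.

    The target covariance is ``I + edge_weight * A``, eigenvalue-clipped
    at 1e-6 to guarantee positive definiteness; the sampled series is
    scaled by ``noise_sd`` (which leaves all correlations unchanged).
    Adjacent node pairs therefore have population correlation
    ``edge_weight`` (up to the clipping projection) and non-adjacent
    pairs 0.
    """
    if n_timepoints < 2:
        raise ValidationError("n_timepoints must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = graph.adjacency.astype(float)
    cov = np.eye(a.shape[0]) + edge_weight * a
    eigvals, eigvecs = np.linalg.eigh(cov)
    clipped = np.clip(eigvals, 1e-6, None)
    if clipped.min() <= 0:
        raise ComputationError(
            f"covariance not positive definite after projection "
            f"(min eigenvalue {clipped.min():.3e})"
        )
    factor = eigvecs * np.sqrt(clipped)
    data = noise_sd * (factor @ rng.standard_normal((a.shape[0], n_timepoints)))
    return SubjectTimeSeries(
        data=data,
        tr_seconds=tr_seconds,
        roi_labels=graph.node_labels,
        subject_id=subject_id,
    )


def population_correlation(
    graph: BinaryGraph, edge_weight: float
) -> np.ndarray:
    """Exact population correlation matrix implied by the construction."""
    a = graph.adjacency.astype(float)
    cov = np.eye(a.shape[0]) + edge_weight * a
    eigvals, eigvecs = np.linalg.eigh(cov)
    cov = (eigvecs * np.clip(eigvals, 1e-6, None)) @ eigvecs.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def generate_motion_trace(
    n_timepoints: int,
    spike_frames: tuple[int, ...] = (),
    spike_amplitude_mm: float = 0.6,
    seed: int | np.random.Generator = 0,
    drift_step: float = 0.01,
    subject_id: str | None = None,
) -> MotionTrace:
    """Rigid-body motion: slow random-walk drift plus step displacements.

    Each of the six parameters drifts by a uniform increment in
    ``[-drift_step, drift_step]`` per frame (keeping baseline FD well
    under any realistic scrubbing threshold for the default step);
    every spike frame adds a persistent step of ``spike_amplitude_mm``
    to the x translation, so FD exceeds the amplitude at exactly those
    frames. Frame indices are 0-based; frame 0 cannot spike (FD is
    undefined there).
    """
    if any(not 1 <= f < n_timepoints for f in spike_frames):
        raise ValidationError(
            "spike frames must lie in [1, n_timepoints): FD is undefined at "
            "frame 0"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    increments = rng.uniform(-drift_step, drift_step, size=(n_timepoints, 6))
    increments[0] = 0.0
    params = np.cumsum(increments, axis=0)
    for f in spike_frames:
        params[f:, 0] += spike_amplitude_mm
    return MotionTrace(params=params, subject_id=subject_id)


def generate_behavioral_scores(
    nodal_values: np.ndarray,
    slope: float = 1.0,
    noise_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
    intercept: float = 70.0,
) -> np.ndarray:
    """Linear behavioral scores: ``intercept + slope * value + noise``.

    The population correlation between scores and nodal values is
    ``slope * sd(values) / sqrt(slope^2 var(values) + noise_sd^2)``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(nodal_values, dtype=float)
    return intercept + slope * values + noise_sd * rng.standard_normal(values.shape)


def generate_dataset(spec: GroundTruthSpec) -> SyntheticDataset:
    """Realize one full two-group study from a ground-truth specification.

    Seed scheme: ``SeedSequence(spec.seed)`` spawns
    ``[subjects, behavior, ages]``; each subject's stream spawns
    ``[graph, timeseries, motion]`` in that order, so any stage can be
    regenerated in isolation.
    """
    n_per = spec.n_subjects_per_group
    master = np.random.SeedSequence(spec.seed)
    subjects_ss, behavior_ss, ages_ss = master.spawn(3)
    subject_streams = subjects_ss.spawn(2 * n_per)

    timeseries: list[SubjectTimeSeries] = []
    motions: list[MotionTrace] = []
    graphs: list[BinaryGraph] = []
    rows = []
    age_rng = np.random.default_rng(ages_ss)
    for idx, stream in enumerate(subject_streams):
        group = "A" if idx < n_per else "B"
        sid = f"sub-{idx + 1:03d}"
        graph_ss, ts_ss, motion_ss = stream.spawn(3)
        graph_rng = np.random.default_rng(graph_ss)
        graph = generate_small_world_graph(
            spec.n_nodes, spec.k, spec.beta,
            seed=int(graph_ss.generate_state(1, dtype=np.uint32)[0] % (2**31)),
        )
        if group == "B" and spec.affected_nodes and spec.degradation_fraction > 0:
            graph = degrade_nodes(
                graph, spec.affected_nodes, spec.degradation_fraction, graph_rng
            )
        ts = graph_to_timeseries(
            graph, spec.n_timepoints, spec.edge_weight, spec.noise_sd,
            seed=np.random.default_rng(ts_ss), tr_seconds=spec.tr_seconds,
            subject_id=sid,
        )
        motion_rng = np.random.default_rng(motion_ss)
        candidates = np.flatnonzero(
            motion_rng.random(spec.n_timepoints) < spec.spike_probability
        )
        spikes = tuple(int(f) for f in candidates if f >= 1)
        motion = generate_motion_trace(
            spec.n_timepoints, spikes, spec.spike_amplitude_mm,
            seed=motion_rng, subject_id=sid,
        )
        graphs.append(graph)
        timeseries.append(ts)
        motions.append(motion)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": float(np.round(age_rng.normal(16.0, 0.5), 1)),
                "true_spike_frames": ",".join(map(str, spikes)),
            }
        )
    manifest = pd.DataFrame(rows)

    # behavioral scores driven by the reference node's degree in the
    # subject's true graph
    ref = spec.reference_node
    nodal_values = np.array([g.degrees()[ref] for g in graphs], dtype=float)
    behavior_rng = np.random.default_rng(behavior_ss)
    for column in SCORE_COLUMNS:
        manifest[f"bis_{column}"] = np.round(
            generate_behavioral_scores(
                nodal_values,
                slope=spec.behavior_slope,
                noise_sd=spec.behavior_noise_sd,
                seed=behavior_rng,
                intercept=_SCORE_INTERCEPTS[column],
            ),
            2,
        )
    return SyntheticDataset(
        spec=spec,
        timeseries=tuple(timeseries),
        motions=tuple(motions),
        true_graphs=tuple(graphs),
        manifest=manifest,
    )
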