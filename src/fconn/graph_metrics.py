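"""Global and nodal graph statistics for binary brain networks.

Implements the small-world toolbox: clustering coefficient, shortest
path length, global/local/nodal efficiency, betweenness centrality,
degree-preserving (Markov-chain double-edge-swap) null networks, the
normalized small-world indices gamma, lambda and sigma, the trapezoidal
AUC of a metric across the sparsity grid, and cost efficiency.

Conventions for imperfectly connected graphs (networks at low sparsity
may fragment):

* ``1/inf = 0`` in every efficiency sum;
* infinite distances are excluded from nodal path-length means, with
  the exclusion count reported; a node with no finite distance at all
  has an undefined (NaN) path length and is dropped from ``L_p`` with a
  warning;
* the clustering coefficient of a degree-0/1 node is 0, keeping ``C_p``
  well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from fconn.errors import ComputationError, ValidationError
from fconn.network import BinaryGraph, SparsityGrid

__all__ = [
    "clustering",
    "shortest_paths",
    "path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "rewire_preserving_degree",
    "small_world_indices",
    "SmallWorldResult",
    "auc",
    "cost_efficiency",
    "CostEfficiencyResult",
    "nodal_metrics_table",
    "global_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eglo", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def _adj(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency
    return BinaryGraph(adjacency=np.asarray(graph)).adjacency


def clustering(graph: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients ``C_i`` and their mean ``C_p``.

    ``C_i`` is the number of edges among node i's neighbors divided by
    the ``K_i (K_i - 1) / 2`` pairs of neighbors; 0 for degree < 2.
    """
    a = _adj(graph).astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c, float(c.mean())


def shortest_paths(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    """All-pairs hop-count distance matrix (BFS); unreachable pairs are inf."""
    a = _adj(graph)
    return _csgraph_shortest_path(
        csr_matrix(a), method="D", unweighted=True, directed=False
    )


def path_length(
    graph: BinaryGraph | np.ndarray,
    distances: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int]:
    """Nodal mean shortest path lengths ``L_i`` and their mean ``L_p``.

    Infinite distances are excluded from each node's mean; the third
    return value counts the excluded ordered pairs. A node reaching no
    other node gets ``L_i = NaN`` and is excluded from ``L_p`` with a
    warning.
    """
    d = shortest_paths(graph) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int((off & ~finite).sum())
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(counts > 0, sums / counts, np.nan)
    defined = ~np.isnan(li)
    if not defined.all():
        warnings.warn(
            f"{int((~defined).sum())} node(s) have no finite distances; "
            "excluded from L_p",
            stacklevel=2,
        )
    if not defined.any():
        return li, float("nan"), n_excluded
    return li, float(li[defined].mean()), n_excluded


def global_efficiency(
    graph: BinaryGraph | np.ndarray,
    distances: np.ndarray | None = None,
) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    d = shortest_paths(graph) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(
    graph: BinaryGraph | np.ndarray,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node efficiency: mean of ``1/d(i, j)`` over ``j != i`` (1/inf = 0).

    Its mean over nodes equals the global efficiency exactly.
    """
    d = shortest_paths(graph) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    The subgraph induced on node i's neighbors (i itself excluded)
    measures how well i's neighborhood communicates if i is removed — a
    fault-tolerance summary. Nodes with fewer than 2 neighbors
    contribute 0.
    """
    a = _adj(graph)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def betweenness(
    graph: BinaryGraph | np.ndarray, normalized: bool = False
) -> np.ndarray:
    """Brandes betweenness centrality ``BC_i``.

    By default the unnormalized sum over unordered pairs of the fraction
    of shortest s–t paths passing through i; with ``normalized=True``
    divided by ``(N-1)(N-2)/2``.
    """
    a = _adj(graph)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([bc[i] for i in range(a.shape[0])])


def rewire_preserving_degree(
    graph: BinaryGraph | np.ndarray,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> BinaryGraph:
    """Degree-preserving randomization by Markov-chain double-edge swaps.

    Repeatedly picks two edges (a, b), (c, d) and replaces them with
    (a, d), (c, b), rejecting any move that would create a self-loop or
    a duplicate edge. Degree sequence and edge count are invariant.

    ``n_swaps`` defaults to 10x the edge count (a standard mixing
    budget). If fewer than the requested swaps can be performed within
    ``100 * n_swaps`` attempts, a warning is raised and the partially
    randomized graph is returned.
    """
    a = _adj(graph)
    labels = graph.node_labels if isinstance(graph, BinaryGraph) else ()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ii, jj = np.nonzero(np.triu(a, k=1))
    m = ii.size
    if m < 2:
        raise ValidationError("rewiring requires at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * m
    adj = a.astype(bool).copy()
    edges = np.column_stack([ii, jj])  # mutable edge register
    swaps_done = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    while swaps_done < n_swaps and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if rng.random() < 0.5:
            c1, d1 = d1, c1
        # propose (a1, d1) and (c1, b1)
        if a1 == d1 or c1 == b1:
            continue
        if adj[a1, d1] or adj[c1, b1]:
            continue
        adj[a1, b1] = adj[b1, a1] = False
        adj[c1, d1] = adj[d1, c1] = False
        adj[a1, d1] = adj[d1, a1] = True
        adj[c1, b1] = adj[b1, c1] = True
        edges[e1] = sorted((a1, d1))
        edges[e2] = sorted((c1, b1))
        swaps_done += 1
    if swaps_done < n_swaps:
        warnings.warn(
            f"only {swaps_done}/{n_swaps} swaps performed within "
            f"{max_attempts} attempts; returning partially randomized graph",
            stacklevel=2,
        )
    return BinaryGraph(adjacency=adj.astype(np.uint8), node_labels=labels)


@dataclass(frozen=True)
class SmallWorldResult:
    gamma: float
    lam: float
    sigma: float
    c_random: float
    l_random: float
    n_random: int


def small_world_indices(
    graph: BinaryGraph | np.ndarray,
    n_random: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
) -> SmallWorldResult:
    """Normalized small-world indices against degree-matched nulls.

    gamma = C_p / mean(C_random), lambda = L_p / mean(L_random),
    sigma = gamma / lambda, where the null statistics are means over
    ``n_random`` degree-preserving rewired surrogates. sigma > 1
    (operationally > 1.1) indicates small-world organisation: higher
    clustering than random at comparable path length.

    A null whose ``L_p`` comes out undefined (fully fragmented) is
    regenerated with a fresh sub-seed, at most 10 times.
    """
    a = _adj(graph)
    _, cp = clustering(a)
    _, lp, _ = path_length(a)
    if not np.isfinite(lp):
        raise ComputationError("L_p undefined for the observed graph")
    m = int(a.sum()) // 2
    children = np.random.SeedSequence(seed).spawn(n_random)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for idx, child in enumerate(children):
        for retry, grandchild in enumerate(child.spawn(10)):
            rng = np.random.default_rng(grandchild)
            null = rewire_preserving_degree(a, n_swaps=swap_factor * m, seed=rng)
            _, c_null = clustering(null.adjacency)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, l_null, _ = path_length(null.adjacency)
            if np.isfinite(l_null):
                c_rand[idx] = c_null
                l_rand[idx] = l_null
                break
        else:
            raise ComputationError(
                "could not generate a null network with defined L_p in 10 tries"
            )
    gamma = cp / c_rand.mean()
    lam = lp / l_rand.mean()
    return SmallWorldResult(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(gamma / lam),
        c_random=float(c_rand.mean()),
        l_random=float(l_rand.mean()),
        n_random=n_random,
    )


def auc(values: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid:
    ``sum_k [Y(S_k) + Y(S_{k+1})] * dS / 2``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(grid),):
        raise ValidationError(
            f"curve has {values.shape} values for a grid of {len(grid)}"
        )
    return float(((values[:-1] + values[1:]) * grid.step / 2.0).sum())


@dataclass(frozen=True)
class CostEfficiencyResult:
    """E_glo - cost across the grid; positive values mark an economical network."""

    values: np.ndarray
    argmax_sparsity: float
    max_value: float
    tie: bool


def cost_efficiency(
    eglo_values: np.ndarray, grid: SparsityGrid
) -> CostEfficiencyResult:
    """Pointwise ``E_glo - sparsity`` and the grid point maximizing it.

    Ties take the smallest sparsity and are flagged.
    """
    eglo_values = np.asarray(eglo_values, dtype=float)
    if eglo_values.shape != (len(grid),):
        raise ValidationError("E_glo curve does not match the grid")
    diff = eglo_values - grid.values
    best = int(np.argmax(diff))
    tie = bool(np.sum(np.isclose(diff, diff[best], atol=1e-12)) > 1)
    return CostEfficiencyResult(
        values=diff,
        argmax_sparsity=float(grid.values[best]),
        max_value=float(diff[best]),
        tie=tie,
    )


def nodal_metrics_table(graph: BinaryGraph | np.ndarray) -> dict[str, np.ndarray]:
    """All nodal statistics of one graph in a single pass.

    Returns arrays keyed ``degree``, ``clustering``, ``path_length``,
    ``nodal_efficiency``, ``betweenness``.
    """
    a = _adj(graph)
    d = shortest_paths(a)
    c, _ = clustering(a)
    li, _, _ = path_length(a, distances=d)
    return {
        "degree": a.sum(axis=1).astype(float),
        "clustering": c,
        "path_length": li,
        "nodal_efficiency": nodal_efficiency(a, distances=d),
        "betweenness": betweenness(a),
    }


def global_metrics(
    graph: BinaryGraph | np.ndarray,
    n_random: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """The six global properties plus sigma for one graph.

    Keys: ``Cp, Lp, Eglo, Eloc, gamma, lambda, sigma``.
    """
    a = _adj(graph)
    d = shortest_paths(a)
    _, cp = clustering(a)
    _, lp, _ = path_length(a, distances=d)
    sw = small_world_indices(a, n_random=n_random, seed=seed)
    return {
        "Cp": cp,
        "Lp": lp,
        "Eglo": global_efficiency(a, distances=d),
        "Eloc": local_efficiency(a),
        "gamma": sw.gamma,
        "lambda": sw.lam,
        "sigma": sw.sigma,
    }
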