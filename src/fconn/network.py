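"""Connectivity-matrix construction and sparsity thresholding.

A subject's network is built by Pearson-correlating every pair of ROI
time series, applying the Fisher r-to-z transform, and binarizing the
|z| matrix at a *sparsity* (cost): the fraction of realized edges out
of all possible node pairs. Working at fixed sparsity rather than at a
fixed correlation threshold guarantees that networks compared across
groups have the same number of edges.

Edges are ranked by |z|, so strong negative correlations yield edges —
deliberate, since global-signal regression (which manufactures spurious
negative correlations) is not part of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fconn.errors import ComputationError, ValidationError
from fconn.prep import SubjectTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "SparsityGrid",
    "correlation_matrix",
    "binarize_at_sparsity",
    "minimum_sparsity",
    "maximum_sparsity",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of Fisher-transformed correlations.

    The diagonal is stored as 0 and never participates in edge ranking.
    """

    z: np.ndarray
    node_labels: tuple[str, ...] = ()
    subject_id: str | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValidationError(f"connectivity matrix must be square; got {z.shape}")
        if not np.allclose(z, z.T, atol=1e-12, equal_nan=False):
            raise ValidationError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(z[~np.eye(z.shape[0], dtype=bool)])):
            raise ValidationError("off-diagonal entries must be finite")
        z = z.copy()
        np.fill_diagonal(z, 0.0)
        object.__setattr__(self, "z", z)
        labels = tuple(self.node_labels) or tuple(
            f"ROI{i + 1}" for i in range(z.shape[0])
        )
        if len(labels) != z.shape[0]:
            raise ValidationError("node label count does not match matrix size")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted, simple graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square; got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency must have a zero diagonal (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))
        labels = tuple(self.node_labels) or tuple(
            f"ROI{i + 1}" for i in range(a.shape[0])
        )
        if len(labels) != a.shape[0]:
            raise ValidationError("node label count does not match matrix size")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def sparsity(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> list[tuple[int, int]]:
        """Upper-triangle edges as 0-based (i, j) pairs, i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing, uniformly spaced sparsity thresholds."""

    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValidationError("sparsity grid needs at least 2 points")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise ValidationError("sparsity grid must be strictly increasing")
        if not np.allclose(diffs, self.step, atol=1e-9):
            raise ValidationError("sparsity grid must be uniformly spaced")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float = 0.01
                   ) -> "SparsityGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(values=start + step * np.arange(n), step=step)

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


#: The grid used throughout for 90-node networks: 0.11 to 0.44, step 0.01.
def default_grid() -> SparsityGrid:
    return SparsityGrid.from_range(0.11, 0.44, 0.01)


def correlation_matrix(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs, Fisher r-to-z transformed.

    Raises for zero-variance ROIs (undefined correlation) and for
    off-diagonal |r| = 1 (duplicate series make z infinite).
    """
    if ts.n_frames < 3:
        raise ValidationError("correlation requires at least 3 retained frames")
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_labels[i] for i in dead]
        raise ComputationError(
            f"zero-variance ROI(s) {names} for subject {ts.subject_id!r}"
        )
    r = np.corrcoef(ts.data)
    off = ~np.eye(ts.n_rois, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-15):
        ii, jj = np.nonzero((np.abs(r) >= 1.0 - 1e-15) & off)
        pair = (ts.roi_labels[ii[0]], ts.roi_labels[jj[0]])
        raise ComputationError(
            f"degenerate |r|=1 between ROIs {pair} for subject {ts.subject_id!r}"
        )
    with np.errstate(divide="ignore"):  # diagonal r=1 -> inf, zeroed below
        z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, node_labels=ts.roi_labels,
                              subject_id=ts.subject_id)


def _ranked_pairs(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by decreasing |z|, ties by (i, j)."""
    n = z.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    strength = np.abs(z[ii, jj])
    # lexsort: last key is primary; i then j break ties deterministically
    order = np.lexsort((jj, ii, -strength))
    return ii[order], jj[order]


def binarize_at_sparsity(cm: ConnectivityMatrix, sparsity: float) -> BinaryGraph:
    """Keep the K = round(sparsity * N(N-1)/2) strongest |z| edges.

    Ties at the K-th rank are broken by lexicographic (i, j) order, so
    the result is deterministic and the edge sets across a grid of
    sparsities are nested.
    """
    if not 0 < sparsity < 1:
        raise ValidationError(f"sparsity must be in (0, 1); got {sparsity}")
    n = cm.n_nodes
    n_possible = n * (n - 1) // 2
    k = int(round(sparsity * n_possible))
    if k == 0:
        raise ComputationError(
            f"sparsity {sparsity} yields an empty graph on {n} nodes"
        )
    ii, jj = _ranked_pairs(cm.z)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:k], jj[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, node_labels=cm.node_labels)


def minimum_sparsity(n_nodes: int, step: float = 0.01) -> float:
    """Smallest grid sparsity at which the mean degree exceeds 2 ln(N).

    At sparsity ``s`` the mean degree of an N-node network is
    ``s * (N - 1)``; the criterion requires it to exceed ``2 ln N`` so
    that the network is dense enough for stable graph statistics.
    """
    if n_nodes < 4:
        raise ValidationError("minimum_sparsity requires at least 4 nodes")
    target = 2.0 * np.log(n_nodes)
    k = 1
    while True:
        s = round(k * step, 12)
        if s >= 1:
            raise ComputationError(
                f"no sparsity below 1 satisfies the mean-degree criterion "
                f"for N={n_nodes}"
            )
        if s * (n_nodes - 1) > target:
            return s
        k += 1


def maximum_sparsity(
    sigma: np.ndarray,
    grid: SparsityGrid,
    sigma_floor: float = 1.1,
) -> float:
    """Largest grid sparsity up to which every subject stays small-world.

    ``sigma`` is a (n_subjects, n_grid) table of small-worldness values.
    The returned sparsity is the last grid point such that
    ``min over subjects of sigma > sigma_floor`` holds at it and at every
    smaller grid point; the criterion failing already at the first grid
    point is an error (the grid itself is unusable).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[1] != len(grid):
        raise ValidationError(
            f"sigma table shape {sigma.shape} does not match grid of {len(grid)}"
        )
    ok = (sigma > sigma_floor).all(axis=0)
    if not ok[0]:
        raise ComputationError(
            f"small-worldness criterion (> {sigma_floor}) fails at the first "
            f"grid point {grid.values[0]}; choose a different grid"
        )
    bad = np.flatnonzero(~ok)
    last = bad[0] - 1 if bad.size else len(grid) - 1
    return float(grid.values[last])
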