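"""Independent brute-force oracles for graph statistics.

Deliberately naive: Floyd–Warshall triple loops for distances, literal
neighbor-pair counting for clustering, and shortest-path counting via
walk counts (a length-d walk between nodes at distance d is necessarily
a shortest path) for betweenness. Nothing here shares code with the
package implementations.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def fw_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:]
        )
        c[i] = links / (k * (k - 1) / 2)
    return c


def brute_path_length(adj: np.ndarray) -> tuple[np.ndarray, float]:
    d = fw_distances(adj)
    n = adj.shape[0]
    li = np.full(n, np.nan)
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and d[i, j] < INF]
        if finite:
            li[i] = sum(finite) / len(finite)
    defined = li[~np.isnan(li)]
    return li, (defined.mean() if defined.size else float("nan"))


def brute_global_efficiency(adj: np.ndarray) -> float:
    d = fw_distances(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i, j]
        for i in range(n) for j in range(n)
        if i != j and d[i, j] < INF
    )
    return total / (n * (n - 1))


def brute_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = fw_distances(adj)
    n = adj.shape[0]
    e = np.zeros(n)
    for i in range(n):
        e[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and d[i, j] < INF
        ) / (n - 1)
    return e


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness via walk counting.

    The number of shortest s-t paths equals the number of length-d(s,t)
    walks (a walk that short cannot revisit a node); paths through i
    factor as sigma(s,i) * sigma(i,t) when d(s,i) + d(i,t) = d(s,t).
    """
    n = adj.shape[0]
    d = fw_distances(adj)
    powers = [np.eye(n, dtype=np.int64)]
    a = adj.astype(np.int64)
    for _ in range(n):
        powers.append(powers[-1] @ a)

    def sigma(u: int, v: int) -> int:
        if d[u, v] == INF:
            return 0
        return int(powers[int(d[u, v])][u, v])

    bc = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or d[s, t] == INF:
                    continue
                if d[s, i] + d[i, t] == d[s, t]:
                    bc[i] += sigma(s, i) * sigma(i, t) / sigma(s, t)
    return bc


def enumerate_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by literally enumerating every simple path (tiny n only)."""
    n = adj.shape[0]
    d = fw_distances(adj)

    def all_paths(s: int, t: int) -> list[list[int]]:
        out = []

        def extend(path: list[int]) -> None:
            last = path[-1]
            if last == t:
                out.append(path)
                return
            if len(path) - 1 >= d[s, t]:
                return
            for nxt in range(n):
                if adj[last, nxt] and nxt not in path:
                    extend(path + [nxt])

        extend([s])
        return [p for p in out if len(p) - 1 == d[s, t]]

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if d[s, t] == INF or d[s, t] == 0:
                continue
            paths = all_paths(s, t)
            for i in range(n):
                if i == s or i == t:
                    continue
                through = sum(1 for p in paths if i in p)
                bc[i] += through / len(paths)
    return bc


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(np.uint8)
    return adj


def random_connected_graph(
    max_nodes: int, rng: np.random.Generator
) -> np.ndarray:
    while True:
        n = int(rng.integers(4, max_nodes + 1))
        adj = random_graph(n, float(rng.uniform(0.25, 0.9)), rng)
        d = fw_distances(adj)
        if np.isfinite(d).all():
            return adj
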