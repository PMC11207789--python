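"""Independent brute-force oracles for small graphs.

Deliberately naive: Floyd-Warshall distances, betweenness by DFS
enumeration of shortest paths restricted to the shortest-path DAG, and
a triple-loop clustering evaluation. Shares no path-finding code with
the package (which uses scipy Dijkstra / networkx Brandes).
"""

from __future__ import annotations

import numpy as np

TOL = 1e-10


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs distances with edge length = 1/weight."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def strength(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    return np.array([sum(weights[i, j] for j in range(n)) for i in range(n)])


def nodal_path_length(weights: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weights)
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        out[i] = np.mean(vals) if vals else 0.0
    return out


def global_efficiency(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = weights.shape[0]
    if n < 2:
        return 0.0
    vals = [
        (1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0)
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def _shortest_paths(weights: np.ndarray, d: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Enumerate all shortest s->t paths by DFS restricted to edges on
    some shortest path (d[s,x] + len(x,y) + d[y,t] == d[s,t])."""
    n = weights.shape[0]
    target = d[s, t]
    if not np.isfinite(target):
        return []
    paths: list[list[int]] = []

    def dfs(node: int, acc: float, path: list[int]) -> None:
        if node == t:
            paths.append(path[:])
            return
        for nxt in range(n):
            if weights[node, nxt] <= 0 or nxt in path:
                continue
            step = 1.0 / weights[node, nxt]
            if abs(acc + step + d[nxt, t] - target) < TOL:
                path.append(nxt)
                dfs(nxt, acc + step, path)
                path.pop()

    dfs(s, 0.0, [s])
    return paths


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, endpoints excluded, fractional ties,
    summed over unordered source-target pairs (undirected convention)."""
    n = weights.shape[0]
    d = floyd_warshall(weights)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _shortest_paths(weights, d, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def onnela_clustering(weights: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the Onnela form on
    max-normalized weights."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w = weights / wmax
    c = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if weights[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def kendall_tau_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """Tau-b by explicit enumeration of all pairs."""
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (conc - disc) / denom


def random_connected_weights(
    rng: np.random.Generator, n: int, density: float = 0.5
) -> np.ndarray:
    """Random symmetric weighted adjacency, connected via a random
    spanning tree plus density-sampled extra edges."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        w[a, b] = w[b, a] = rng.uniform(0.2, 2.0)
    iu, ju = np.triu_indices(n, k=1)
    extra = rng.random(iu.size) < density
    for a, b in zip(iu[extra], ju[extra]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.uniform(0.2, 2.0)
    return w
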