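"""Weighted nodal and global graph metrics.

Conventions (standard for tractography-weighted connectomes):

- strength (weighted degree): row sum of the adjacency.
- edge length for shortest paths: reciprocal weight, so stronger
  connections are topologically closer.
- nodal path length: mean shortest-path distance to reachable others
  (disconnected pairs omitted from the mean).
- betweenness: weighted Brandes betweenness, endpoints excluded, ties
  split fractionally, unnormalized.
- global efficiency: mean over ordered node pairs of 1/distance, with 0
  for disconnected pairs.
- clustering: Onnela geometric-mean form on weights normalized by the
  matrix maximum; 0 for nodes of binary degree < 2.
"""

from __future__ import annotations

import logging

import igraph
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .containers import ConnectomeMatrix

log = logging.getLogger("connectodiff")

METRICS = ("degree", "betweenness", "clustering", "path_length")


def weighted_degree(m: ConnectomeMatrix) -> np.ndarray:
    """Nodal strength: sum of incident edge weights."""
    return m.weights.sum(axis=1)


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with length = 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def shortest_path_metrics(
    m: ConnectomeMatrix,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(nodal path length, nodal betweenness, global efficiency).

    Nodal path length is the mean distance from a node to the others it
    can reach; betweenness counts shortest source-target paths through
    the node (fractional for ties, endpoints excluded, unnormalized);
    global efficiency averages 1/distance over all ordered pairs,
    scoring 0 for disconnected pairs.
    """
    n = m.n_nodes
    dist = _distance_matrix(m.weights)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.all() and off.any():
        log.info(
            "subject %s: %d disconnected ordered pairs omitted from path length",
            m.subject_id,
            int((~finite & off).sum()),
        )

    path_length = np.zeros(n)
    for i in range(n):
        reach = finite[i]
        path_length[i] = dist[i, reach].mean() if reach.any() else 0.0

    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    global_efficiency = float(inv[off].mean()) if n > 1 else 0.0

    iu, ju = np.nonzero(np.triu(m.weights, 1))
    g = igraph.Graph(n, list(zip(iu.tolist(), ju.tolist())), directed=False)
    lengths = (1.0 / m.weights[iu, ju]).tolist()
    betweenness = np.asarray(g.betweenness(weights=lengths), dtype=float)
    return path_length, betweenness, global_efficiency


def clustering_coefficient(m: ConnectomeMatrix) -> np.ndarray:
    """Onnela weighted clustering on max-normalized weights.

    C_i = sum_{j,h} (w_ij w_ih w_jh)^{1/3} / (k_i (k_i - 1)) with k_i
    the binary degree; C_i = 0 when k_i < 2.
    """
    w = m.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(m.n_nodes)
    cube = np.cbrt(w / wmax)
    # diag of cube^3 counts weighted triangles through each node (x2)
    tri = np.einsum("ij,jk,ki->i", cube, cube, cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def global_network_average(m: ConnectomeMatrix) -> float:
    """Mean nodal strength = 2 * (sum of upper-triangle weights) / N.

    This is the network-based global average of the edge weight metric
    (e.g. global average FA of the connectome).
    """
    return float(weighted_degree(m).mean())


def node_metrics(m: ConnectomeMatrix) -> dict[str, np.ndarray]:
    """All four nodal metrics used by the composite hubness score."""
    pl, bc, _ = shortest_path_metrics(m)
    return {
        "degree": weighted_degree(m),
        "betweenness": bc,
        "clustering": clustering_coefficient(m),
        "path_length": pl,
    }


def global_metrics(m: ConnectomeMatrix) -> dict[str, float]:
    """Per-subject global summaries: average degree and global efficiency."""
    _, _, eff = shortest_path_metrics(m)
    return {
        "average_degree": global_network_average(m),
        "global_efficiency": eff,
    }
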