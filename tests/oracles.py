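"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: Floyd–Warshall all-pairs distances, exhaustive triangle
enumeration, exhaustive shortest-path enumeration by DFS, and O(n^2)
pairwise-distance graph construction.  None of these share code paths with
the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_REL_TOL = 1e-9


def distance_matrix(g) -> tuple[np.ndarray, list]:
    """Floyd–Warshall all-pairs weighted distances. Returns (D, node order)."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        i, j = idx[u], idx[v]
        dist[i, j] = dist[j, i] = min(dist[i, j], w)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist, nodes


def global_efficiency_bruteforce(g) -> float:
    """Mean of 1/d over ordered pairs; disconnected pairs contribute 0."""
    dist, _ = distance_matrix(g)
    n = len(dist)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def average_clustering_bruteforce(g) -> float:
    """Per-node triangle counts by enumerating all node triples."""
    nodes = list(g.nodes)
    triangles = dict.fromkeys(nodes, 0)
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            triangles[a] += 1
            triangles[b] += 1
            triangles[c] += 1
    coeffs = []
    for v in nodes:
        k = g.degree(v)
        coeffs.append(0.0 if k < 2 else 2.0 * triangles[v] / (k * (k - 1)))
    return float(np.mean(coeffs))


def _all_simple_paths(g, source, target):
    """DFS enumeration of simple paths with their total weights."""
    stack = [(source, [source], 0.0)]
    while stack:
        node, path, weight = stack.pop()
        if node == target:
            yield path, weight
            continue
        for nbr in g.neighbors(node):
            if nbr not in path:
                stack.append(
                    (nbr, path + [nbr], weight + g.edges[node, nbr].get("weight", 1.0))
                )


def average_betweenness_bruteforce(g) -> float:
    """Betweenness by exhaustive shortest-path enumeration.

    For each unordered pair (s, t), all simple paths are enumerated, the
    minimal weight identified, and paths within relative tolerance of the
    minimum counted as shortest.  Normalization: (n-1)(n-2)/2.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 3:
        return 0.0
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(g, s, t))
        if not paths:
            continue
        dmin = min(w for _, w in paths)
        shortest = [p for p, w in paths if w <= dmin * (1 + _REL_TOL) + 1e-12]
        sigma = len(shortest)
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return float(np.mean([bc[v] / norm for v in nodes]))


def pairwise_edge_set(skeleton: np.ndarray) -> set[tuple[tuple[int, int], ...]]:
    """O(n^2) graph construction: threshold all pairwise Euclidean distances
    at sqrt(2) (+1e-9 guard).  Returns edges as sets of coordinate pairs."""
    coords = [tuple(map(int, rc)) for rc in np.argwhere(skeleton)]
    edges = set()
    for (r1, c1), (r2, c2) in itertools.combinations(coords, 2):
        if math.hypot(r1 - r2, c1 - c2) <= math.sqrt(2) + 1e-9:
            edges.add(tuple(sorted(((r1, c1), (r2, c2)))))
    return edges


def zone_of_node(row, col, center_xy, delta_r) -> int:
    """Per-node zone index by direct formula evaluation."""
    x_c, y_c = center_xy
    d = math.hypot(col - x_c, row - y_c)
    return int(d // delta_r) + 1


def tortuosity_all_pairs_bruteforce(g) -> float:
    """Exact all-pairs mean tortuosity from Floyd–Warshall distances."""
    dist, nodes = distance_matrix(g)
    ratios = []
    for i, u in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if not np.isfinite(dist[i, j]):
                continue
            v = nodes[j]
            dx = g.nodes[u]["col"] - g.nodes[v]["col"]
            dy = g.nodes[u]["row"] - g.nodes[v]["row"]
            ratios.append(dist[i, j] / math.hypot(dx, dy))
    return float(np.mean(ratios))
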