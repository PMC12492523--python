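"""The eleven topology metrics of the angiogenic pixel graph.

For a weighted undirected graph G = (V, E) extracted from a skeletonized
tubule image we report: node count |V|, edge count |E|, average degree
<k> = (1/|V|) sum deg(v), average clustering coefficient (Watts–Strogatz,
C_v = 2 T_v / (k_v (k_v - 1)), zero for degree < 2), global efficiency
E_glob = (1/(|V|(|V|-1))) sum_{i != j} 1/d_ij with disconnected pairs
contributing zero, average betweenness centrality (normalized by
(|V|-1)(|V|-2)/2), average tortuosity T_ij = L_ij / D_ij over randomly
sampled same-component node pairs (L = along-network shortest path,
D = straight-line Euclidean distance), number of connected components,
largest component size, the connectivity index N_largest / N_total, and
network density ND = 2|E| / (|V|(|V|-1)).

Shortest paths are weighted by the Euclidean edge weights by default
(``MetricConfig.weighted_paths``); hop counts are available as a switch.
Metrics undefined on degenerate graphs (e.g. tortuosity on an edgeless
graph, efficiency/density on a singleton) are reported as NaN sentinels,
never as a fabricated zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

__all__ = [
    "MetricConfig",
    "GraphMetrics",
    "METRIC_NAMES",
    "average_degree",
    "average_clustering",
    "global_efficiency",
    "average_betweenness",
    "average_tortuosity",
    "component_stats",
    "network_density",
    "compute_all_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricConfig:
    """Knobs for the path-based metrics.

    tortuosity_sample_pairs
        Number of distinct same-component node pairs sampled for average
        tortuosity (all pairs are used when fewer exist).
    rng_seed
        Seed of the pair sampler; identical seeds reproduce identical
        tortuosity values bit-for-bit.
    weighted_paths
        Use Euclidean edge weights for shortest paths (default) rather
        than hop counts.
    """

    tortuosity_sample_pairs: int = 100
    rng_seed: int = 0
    weighted_paths: bool = True

    def __post_init__(self) -> None:
        if self.tortuosity_sample_pairs < 1:
            raise ValueError("tortuosity_sample_pairs must be >= 1")


@dataclass
class GraphMetrics:
    """One image's metric record (the columns of the per-image table)."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    global_efficiency: float
    avg_betweenness: float
    avg_tortuosity: float
    n_components: int
    largest_component_size: int
    connectivity_index: float
    network_density: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES: tuple[str, ...] = tuple(f.name for f in fields(GraphMetrics))


def _require_nonempty(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("metric undefined on an empty graph")


def _weight_key(cfg: MetricConfig | None) -> str | None:
    if cfg is None or cfg.weighted_paths:
        return "weight"
    return None


def average_degree(g: nx.Graph) -> float:
    """<k> = 2|E|/|V|."""
    _require_nonempty(g)
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def average_clustering(g: nx.Graph) -> float:
    """Mean Watts–Strogatz clustering coefficient (unweighted triangles)."""
    _require_nonempty(g)
    return float(nx.average_clustering(g))


def global_efficiency(g: nx.Graph, cfg: MetricConfig | None = None) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Pairs in different components contribute 0 (the 1/inf convention), so
    the metric is well defined on fragmented early-timepoint networks.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    weight = _weight_key(cfg)
    if weight is None:
        lengths = nx.all_pairs_shortest_path_length(g)
    else:
        lengths = nx.all_pairs_dijkstra_path_length(g, weight=weight)
    total = 0.0
    for source, dists in lengths:
        for target, d in dists.items():
            if target != source and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def average_betweenness(g: nx.Graph, cfg: MetricConfig | None = None) -> float:
    """Mean betweenness centrality, normalized by (|V|-1)(|V|-2)/2.

    Graphs with fewer than 3 nodes have no interior vertices and return 0.
    """
    _require_nonempty(g)
    if g.number_of_nodes() < 3:
        return 0.0
    bc = nx.betweenness_centrality(g, normalized=True, weight=_weight_key(cfg))
    return float(np.mean(list(bc.values())))


def _node_xy(g: nx.Graph, v) -> tuple[float, float]:
    data = g.nodes[v]
    return float(data["col"]), float(data["row"])


def _sample_same_component_pairs(
    g: nx.Graph, k: int, rng: np.random.Generator
) -> list[tuple[object, object]]:
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    if not comps:
        raise ValueError(
            "no connected node pair exists: graph is fully fragmented"
        )
    pair_counts = [len(c) * (len(c) - 1) // 2 for c in comps]
    total = sum(pair_counts)
    if total <= k:
        return [
            (c[i], c[j])
            for c in comps
            for i in range(len(c))
            for j in range(i + 1, len(c))
        ]
    weights = np.asarray(pair_counts, dtype=float) / total
    pairs: list[tuple[object, object]] = []
    seen: set[tuple[object, object]] = set()
    while len(pairs) < k:
        ci = int(rng.choice(len(comps), p=weights))
        i, j = rng.choice(len(comps[ci]), size=2, replace=False)
        u, v = comps[ci][int(i)], comps[ci][int(j)]
        key = (u, v) if u <= v else (v, u)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def average_tortuosity(g: nx.Graph, cfg: MetricConfig | None = None) -> float:
    """Mean path-length / straight-line-distance ratio over sampled pairs.

    Pairs are drawn uniformly without replacement from same-component
    unordered pairs (tortuosity across components is undefined); each
    ratio is >= 1 up to rounding.  Requires ``row``/``col`` node
    attributes.
    """
    _require_nonempty(g)
    cfg = cfg or MetricConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    pairs = _sample_same_component_pairs(g, cfg.tortuosity_sample_pairs, rng)
    weight = _weight_key(cfg)
    ratios = []
    for u, v in pairs:
        if weight is None:
            path_len = float(nx.shortest_path_length(g, u, v))
        else:
            path_len = float(nx.dijkstra_path_length(g, u, v, weight=weight))
        xu, yu = _node_xy(g, u)
        xv, yv = _node_xy(g, v)
        euclid = math.hypot(xu - xv, yu - yv)
        ratios.append(path_len / euclid)
    return float(np.mean(ratios))


def component_stats(g: nx.Graph) -> tuple[int, int, float]:
    """(number of components, largest component size, connectivity index).

    The connectivity index N_largest / N_total approaches 1 for a fully
    integrated network and drops with fragmentation.
    """
    _require_nonempty(g)
    sizes = [len(c) for c in nx.connected_components(g)]
    largest = max(sizes)
    return len(sizes), largest, largest / g.number_of_nodes()


def network_density(g: nx.Graph) -> float:
    """ND = 2|E| / (|V|(|V|-1))."""
    if g.number_of_nodes() < 2:
        raise ValueError("network density requires at least 2 nodes")
    return float(nx.density(g))


def compute_all_metrics(g: nx.Graph, cfg: MetricConfig | None = None) -> GraphMetrics:
    """Populate the full metric record for one graph.

    Degenerate graphs get NaN sentinels for the undefined entries
    (logged), never silent zeros; an empty graph raises.
    """
    _require_nonempty(g)
    cfg = cfg or MetricConfig()
    n = g.number_of_nodes()

    if n >= 2:
        efficiency = global_efficiency(g, cfg)
        density = network_density(g)
    else:
        efficiency = density = float("nan")
        logger.warning("singleton graph: efficiency and density undefined (NaN)")

    try:
        tortuosity = average_tortuosity(g, cfg)
    except ValueError:
        tortuosity = float("nan")
        logger.warning("fully fragmented graph: tortuosity undefined (NaN)")

    n_comp, largest, conn_index = component_stats(g)
    return GraphMetrics(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        avg_degree=average_degree(g),
        avg_clustering=average_clustering(g),
        global_efficiency=efficiency,
        avg_betweenness=average_betweenness(g, cfg),
        avg_tortuosity=tortuosity,
        n_components=n_comp,
        largest_component_size=largest,
        connectivity_index=conn_index,
        network_density=density,
    )
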