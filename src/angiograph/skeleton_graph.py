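"""Skeletonization and pixel-graph construction.

A binary tubule mask is thinned to its 1-pixel-wide, topology-preserving
centerline, and the skeleton is converted into a weighted undirected graph:
one node per skeleton pixel, an edge between every pair of 8-adjacent
skeleton pixels, weighted by the Euclidean distance between pixel centers
(1 for axial neighbors, sqrt(2) for diagonal neighbors).

Coordinates are (row, col), 0-based, row increasing downward.  For plotting
parity with image axes, x = col and y = row; :func:`node_positions` is the
single conversion point.

The builder scans the fixed half-neighborhood offsets E, SE, S, SW per
pixel — O(n) in skeleton pixels and duplicate-free — which is set-identical
to thresholding the full pairwise Euclidean distance matrix at sqrt(2)
(adjacency is decided on integer Chebyshev distance 1, so no float
tolerance issue arises in practice).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from skimage import morphology

__all__ = ["skeletonize", "build_graph", "node_positions", "SQRT2"]

SQRT2 = math.sqrt(2.0)

# (dr, dc, weight): E, SE, S, SW half-neighborhood; each 8-adjacent pair is
# generated exactly once.
_HALF_NEIGHBORHOOD = (
    (0, 1, 1.0),
    (1, 1, SQRT2),
    (1, 0, 1.0),
    (1, -1, SQRT2),
)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to 1-px-wide centerlines (iterative thinning).

    Topology is preserved: the skeleton has the same number of 8-connected
    components as the mask, and skeleton pixels are a subset of the mask
    foreground.  An empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    return morphology.skeletonize(mask)


def build_graph(skeleton: np.ndarray) -> nx.Graph:
    """Convert a skeleton mask into a weighted undirected pixel graph.

    Nodes are integers 0..n-1 in row-major scan order, each carrying
    ``row`` and ``col`` attributes.  Edges join 8-adjacent skeleton pixels
    with weight equal to the Euclidean inter-pixel distance.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.ndim != 2:
        raise ValueError("expected a 2-D skeleton mask")

    coords = np.argwhere(skeleton)  # row-major order
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}

    g = nx.Graph()
    for i, (r, c) in enumerate(coords):
        g.add_node(i, row=int(r), col=int(c))
    for (r, c), i in index.items():
        for dr, dc, w in _HALF_NEIGHBORHOOD:
            j = index.get((r + dr, c + dc))
            if j is not None:
                g.add_edge(i, j, weight=w)
    return g


def node_positions(g: nx.Graph) -> np.ndarray:
    """(n, 2) array of (x, y) = (col, row) positions, node-id order."""
    return np.array(
        [(g.nodes[v]["col"], g.nodes[v]["row"]) for v in sorted(g.nodes)],
        dtype=float,
    ).reshape(-1, 2)
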