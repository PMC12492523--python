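import math

import networkx as nx
import numpy as np
import pytest

from angiograph.synthetic import toy_skeletons


@pytest.fixture(scope="session")
def toys():
    return toy_skeletons()


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 12) -> nx.Graph:
    """Random sparse graph with grid-like edge weights (1, sqrt 2, or 2)."""
    n = int(rng.integers(4, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.4))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    weights = [1.0, math.sqrt(2.0), 2.0]
    for u, v in g.edges:
        g.edges[u, v]["weight"] = weights[int(rng.integers(3))]
    return g


def random_skeleton_mask(rng: np.random.Generator, shape=(20, 20), density=0.12):
    return rng.random(shape) < density
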