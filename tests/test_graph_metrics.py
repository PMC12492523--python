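"""Topology metrics against hand computations and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from angiograph.graph_metrics import (
    MetricConfig,
    average_betweenness,
    average_clustering,
    average_degree,
    average_tortuosity,
    component_stats,
    compute_all_metrics,
    global_efficiency,
    network_density,
)
from angiograph.skeleton_graph import build_graph
from conftest import random_weighted_graph
from oracles import (
    average_betweenness_bruteforce,
    average_clustering_bruteforce,
    global_efficiency_bruteforce,
    tortuosity_all_pairs_bruteforce,
)

SQRT2 = math.sqrt(2.0)


@pytest.fixture()
def line3(toys):
    return build_graph(toys["line3"])


@pytest.fixture()
def l_triangle(toys):
    return build_graph(toys["l_triangle"])


class TestAverageDegree:
    def test_line3(self, line3):
        assert average_degree(line3) == pytest.approx(4 / 3)

    def test_triangle(self, l_triangle):
        assert average_degree(l_triangle) == 2.0

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node(0, row=0, col=0)
        assert average_degree(g) == 0.0

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            average_degree(nx.Graph())


class TestAverageClustering:
    def test_triangle_is_one(self, l_triangle):
        assert average_clustering(l_triangle) == 1.0

    def test_line_is_zero(self, line3):
        assert average_clustering(line3) == 0.0

    def test_matches_triple_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            g = random_weighted_graph(rng, max_nodes=10)
            assert average_clustering(g) == pytest.approx(
                average_clustering_bruteforce(g), abs=1e-9
            )


class TestGlobalEfficiency:
    def test_line3_weighted(self, line3):
        # ordered-pair inverse distances: 1,1,1,1,1/2,1/2 -> 5/6
        assert global_efficiency(line3) == pytest.approx(5 / 6, abs=1e-12)

    def test_two_isolated_nodes(self):
        g = nx.Graph()
        g.add_nodes_from([(0, {"row": 0, "col": 0}), (1, {"row": 5, "col": 5})])
        assert global_efficiency(g) == 0.0

    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = random_weighted_graph(rng)
            assert global_efficiency(g) == pytest.approx(
                global_efficiency_bruteforce(g), abs=1e-9
            )

    def test_singleton_raises(self):
        g = nx.Graph()
        g.add_node(0)
        with pytest.raises(ValueError):
            global_efficiency(g)


class TestAverageBetweenness:
    def test_line3(self, line3):
        # only the middle node carries the single endpoint-to-endpoint path
        assert average_betweenness(line3) == pytest.approx(1 / 3, abs=1e-12)

    def test_triangle_is_zero(self, l_triangle):
        assert average_betweenness(l_triangle) == 0.0

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            g = random_weighted_graph(rng, max_nodes=10)
            assert average_betweenness(g) == pytest.approx(
                average_betweenness_bruteforce(g), abs=1e-9
            )

    def test_fewer_than_three_nodes(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        assert average_betweenness(g) == 0.0


class TestAverageTortuosity:
    def test_straight_line_is_exactly_one(self, toys):
        g = build_graph(toys["line9"])
        cfg = MetricConfig(tortuosity_sample_pairs=100, rng_seed=0)
        assert average_tortuosity(g, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_triangle_diagonal_pair(self, l_triangle):
        cfg = MetricConfig(tortuosity_sample_pairs=10, rng_seed=0)
        assert average_tortuosity(l_triangle, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_u_shape_matches_all_pairs_oracle(self):
        # U-shaped skeleton: corner-to-corner path L=4 vs straight D=2*sqrt2
        skel = np.zeros((4, 4), dtype=bool)
        skel[0, 0] = skel[1, 0] = skel[2, 0] = skel[2, 1] = skel[2, 2] = True
        g = build_graph(skel)
        expected = tortuosity_all_pairs_bruteforce(g)
        cfg = MetricConfig(tortuosity_sample_pairs=1000, rng_seed=0)
        assert average_tortuosity(g, cfg) == pytest.approx(expected, abs=1e-9)
        # the forced corner pair itself contributes sqrt 2
        corner_ratio = 4.0 / (2 * SQRT2)
        assert corner_ratio == pytest.approx(SQRT2)

    def test_sample_of_everything_equals_exact_mean(self):
        rng = np.random.default_rng(13)
        skel = rng.random((15, 15)) < 0.25
        g = build_graph(skel)
        if not any(len(c) >= 2 for c in nx.connected_components(g)):
            pytest.skip("degenerate draw")
        cfg = MetricConfig(tortuosity_sample_pairs=10**6, rng_seed=1)
        assert average_tortuosity(g, cfg) == pytest.approx(
            tortuosity_all_pairs_bruteforce(g), abs=1e-9
        )

    def test_every_ratio_at_least_one(self):
        rng = np.random.default_rng(14)
        skel = rng.random((20, 20)) < 0.2
        g = build_graph(skel)
        cfg = MetricConfig(tortuosity_sample_pairs=50, rng_seed=2)
        try:
            t = average_tortuosity(g, cfg)
        except ValueError:
            pytest.skip("fully fragmented draw")
        assert t >= 1.0 - 1e-9

    def test_fragmented_graph_raises(self, toys):
        g = build_graph(toys["isolated_pixels"])
        with pytest.raises(ValueError, match="fragmented"):
            average_tortuosity(g, MetricConfig(rng_seed=0))


class TestComponentsAndDensity:
    def test_two_component_fixture(self, toys):
        g = build_graph(toys["two_component"])
        assert component_stats(g) == (2, 3, 0.75)

    def test_connected_graph(self, toys):
        g = build_graph(toys["ring"])
        n = g.number_of_nodes()
        assert component_stats(g) == (1, n, 1.0)

    def test_isolated_pixels(self, toys):
        g = build_graph(toys["isolated_pixels"])
        assert component_stats(g) == (16, 1, 1 / 16)

    def test_density_line3(self, line3):
        assert network_density(line3) == pytest.approx(2 / 3)

    def test_density_triangle_complete(self, l_triangle):
        assert network_density(l_triangle) == 1.0

    def test_density_edgeless(self, toys):
        g = build_graph(toys["isolated_pixels"])
        assert network_density(g) == 0.0

    def test_connectivity_index_nondecreasing_when_bridging(self, toys):
        g = build_graph(toys["two_component"])
        _, _, ci_before = component_stats(g)
        g.add_edge(0, 3, weight=1.0)  # join the two components
        _, _, ci_after = component_stats(g)
        assert ci_after >= ci_before


class TestComputeAll:
    def test_line3_record(self, line3):
        m = compute_all_metrics(line3, MetricConfig(rng_seed=0))
        assert (m.n_nodes, m.n_edges) == (3, 2)
        assert m.avg_degree == pytest.approx(4 / 3)
        assert m.avg_clustering == 0.0
        assert m.global_efficiency == pytest.approx(5 / 6)
        assert m.avg_betweenness == pytest.approx(1 / 3)
        assert m.avg_tortuosity == pytest.approx(1.0)
        assert (m.n_components, m.largest_component_size) == (1, 3)
        assert m.connectivity_index == 1.0
        assert m.network_density == pytest.approx(2 / 3)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(15)
        skel = rng.random((30, 30)) < 0.2
        g = build_graph(skel)
        cfg = MetricConfig(tortuosity_sample_pairs=20, rng_seed=7)
        assert compute_all_metrics(g, cfg) == compute_all_metrics(g, cfg)

    def test_degree_identity_holds(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            g = random_weighted_graph(rng)
            nx.set_node_attributes(g, 0, "row")
            nx.set_node_attributes(g, 0, "col")
            for i, v in enumerate(g.nodes):
                g.nodes[v]["row"], g.nodes[v]["col"] = divmod(i * 3, 7)
            m = compute_all_metrics(g, MetricConfig(rng_seed=0))
            assert m.avg_degree == pytest.approx(2 * m.n_edges / m.n_nodes)

    def test_singleton_gets_nan_sentinels(self):
        g = nx.Graph()
        g.add_node(0, row=2, col=3)
        m = compute_all_metrics(g, MetricConfig(rng_seed=0))
        assert math.isnan(m.global_efficiency)
        assert math.isnan(m.network_density)
        assert math.isnan(m.avg_tortuosity)
        assert m.n_nodes == 1 and m.connectivity_index == 1.0

    def test_relabeling_invariance(self, toys):
        g = build_graph(toys["cross"])
        perm = {v: (v * 7 + 3) % 100 for v in g.nodes}
        h = nx.relabel_nodes(g, perm)
        cfg = MetricConfig(tortuosity_sample_pairs=10**6, rng_seed=0)
        mg, mh = compute_all_metrics(g, cfg), compute_all_metrics(h, cfg)
        for field in ("avg_degree", "avg_clustering", "global_efficiency",
                      "avg_betweenness", "avg_tortuosity", "network_density"):
            assert getattr(mg, field) == pytest.approx(getattr(mh, field), abs=1e-9)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            compute_all_metrics(nx.Graph(), MetricConfig(rng_seed=0))
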