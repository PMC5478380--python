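import math

import numpy as np
import pandas as pd
import pytest

from nestnet import (
    DegenerateGeometryError,
    build_knn_network,
    build_thiessen_network,
    count_links,
    edge_weight,
    node_strength,
    reciprocity,
)
from nestnet.simulate import ScenarioConfig, generate_woodland

from conftest import make_network
from oracles import brute_knn


class TestEdgeWeight:
    def test_known_values(self):
        assert edge_weight(math.e) == pytest.approx(1.0, abs=1e-12)
        assert edge_weight(math.e**2) == pytest.approx(0.5, abs=1e-12)
        assert edge_weight(100.0) == pytest.approx(1 / math.log(100), abs=1e-12)
        assert edge_weight(100.0) == pytest.approx(0.217147, abs=5e-7)

    def test_monotone_decreasing_beyond_clamp(self):
        ds = np.linspace(2.0, 500.0, 200)
        ws = [edge_weight(d) for d in ds]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_clamp_and_domain(self):
        assert edge_weight(0.5) == edge_weight(2.0)  # clamped
        with pytest.raises(ValueError):
            edge_weight(-1.0)
        with pytest.raises(ValueError):
            edge_weight(10.0, d_min=1.0)


class TestKnn:
    def test_line_layout_k1(self, line_tables):
        """Birds at x = 0, 10, 20, 100: nearest-neighbour edges by hand."""
        nestboxes, records, personality = line_tables
        net = build_knn_network(
            records, nestboxes, personality, year=2001, sex="male", k=1,
            restrict_order="restrict_then_construct",
        )
        # m2 is equidistant (10 m) from m1 and m3; the tie goes to the
        # smaller box_id, so m2 -> m1
        assert set(net.graph.edges) == {("m1", "m2"), ("m2", "m1"), ("m3", "m2"), ("m4", "m3")}
        assert net.graph.in_degree("m4") == 0

    def test_line_layout_k3_complete(self, line_tables):
        nestboxes, records, personality = line_tables
        net = build_knn_network(records, nestboxes, personality, 2001, "male", k=3)
        assert net.n_edges == 4 * 3  # k = n-1: complete directed graph

    def test_k_exceeding_n_links_all(self, line_tables):
        nestboxes, records, personality = line_tables
        net = build_knn_network(records, nestboxes, personality, 2001, "male", k=99)
        assert net.n_edges == 12

    def test_construct_then_restrict_keeps_typed_typed_edges(self):
        """5 birds, 2 typed: retained edges are the typed->typed pairs among
        each typed bird's k=3 nearest of all five (enumerated by hand)."""
        nestboxes = pd.DataFrame(
            {"box_id": list("abcde"), "x": [0.0, 10.0, 20.0, 30.0, 40.0],
             "y": [0.0] * 5, "region": ["R"] * 5}
        )
        records = pd.DataFrame(
            {"year": [2001] * 5, "box_id": list("abcde"),
             "male_id": [f"m{i}" for i in range(5)], "female_id": [None] * 5}
        )
        personality = pd.DataFrame(
            {"bird_id": ["m0", "m3"], "sex": ["male"] * 2, "score": [1.0, 2.0]}
        )
        net = build_knn_network(
            records, nestboxes, personality, 2001, "male", k=3,
            restrict_order="construct_then_restrict",
        )
        # m0's 3 nearest of all five: m1,m2,m3 -> typed target m3 kept
        # m3's 3 nearest: m2,m4,m1 -> no typed target
        assert set(net.graph.nodes) == {"m0", "m3"}
        assert set(net.graph.edges) == {("m0", "m3")}

    def test_restrict_then_construct_full_outdegree(self, small_dataset):
        ds = small_dataset
        net = build_knn_network(
            ds.records, ds.nestboxes, ds.personality, year=2001, sex="male",
            k=5, restrict_order="restrict_then_construct",
        )
        n = net.n_nodes
        assert all(d == min(5, n - 1) for _, d in net.graph.out_degree)

    def test_agrees_with_brute_force_scan(self):
        """Implementation matches an O(n^2) hand scan on random layouts."""
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(4, 40))
            pts = rng.uniform(0, 1000, size=(n, 2))
            boxes = [f"b{i:03d}" for i in range(n)]
            nestboxes = pd.DataFrame(
                {"box_id": boxes, "x": pts[:, 0], "y": pts[:, 1], "region": "R"}
            )
            records = pd.DataFrame(
                {"year": 2001, "box_id": boxes,
                 "male_id": [f"m{i:03d}" for i in range(n)], "female_id": None}
            )
            personality = pd.DataFrame(
                {"bird_id": records["male_id"], "sex": "male",
                 "score": rng.normal(size=n)}
            )
            k = int(rng.integers(1, 8))
            net = build_knn_network(records, nestboxes, personality, 2001, "male", k=k)
            expected = {
                (f"m{i:03d}", f"m{j:03d}") for i, j, _ in brute_knn(pts.tolist(), boxes, k)
            }
            assert set(net.graph.edges) == expected
            for i, j, d in brute_knn(pts.tolist(), boxes, k):
                w = net.graph[f"m{i:03d}"][f"m{j:03d}"]["weight"]
                assert w == pytest.approx(1 / math.log(max(d, 2.0)), rel=1e-12)

    def test_distance_tie_broken_by_smaller_box_id(self):
        """Grid corner equidistant to two boxes: smaller box_id wins."""
        nestboxes = pd.DataFrame(
            {"box_id": ["a", "b", "c"], "x": [0.0, 10.0, 0.0],
             "y": [0.0, 0.0, 10.0], "region": "R"}
        )  # b and c both at distance 10 from a
        records = pd.DataFrame(
            {"year": 2001, "box_id": ["a", "b", "c"],
             "male_id": ["m_a", "m_b", "m_c"], "female_id": None}
        )
        personality = pd.DataFrame(
            {"bird_id": ["m_a", "m_b", "m_c"], "sex": "male", "score": [1.0, 2.0, 3.0]}
        )
        net = build_knn_network(records, nestboxes, personality, 2001, "male", k=1)
        assert ("m_a", "m_b") in net.graph.edges  # box 'b' < box 'c'

    def test_single_breeder_yields_empty_network(self, line_tables):
        nestboxes, records, personality = line_tables
        solo = records.iloc[:1]
        net = build_knn_network(solo, nestboxes, personality, 2001, "male", k=3)
        assert net.n_edges == 0

    def test_weight_monotone_in_neighbour_distance(self, small_dataset):
        ds = small_dataset
        net = build_knn_network(ds.records, ds.nestboxes, ds.personality, 2001, "male", k=5)
        for u in net.graph.nodes:
            nbrs = [
                (math.dist((net.graph.nodes[u]["x"], net.graph.nodes[u]["y"]),
                           (net.graph.nodes[v]["x"], net.graph.nodes[v]["y"])),
                 net.graph[u][v]["weight"])
                for v in net.graph.successors(u)
            ]
            nbrs.sort()
            assert all(w1 >= w2 - 1e-12 for (_, w1), (_, w2) in zip(nbrs, nbrs[1:]))


def _tables_from_points(pts, scores=None):
    n = len(pts)
    boxes = [f"b{i:02d}" for i in range(n)]
    nestboxes = pd.DataFrame(
        {"box_id": boxes, "x": [p[0] for p in pts], "y": [p[1] for p in pts], "region": "R"}
    )
    records = pd.DataFrame(
        {"year": 2001, "box_id": boxes, "male_id": [f"m{i:02d}" for i in range(n)],
         "female_id": None}
    )
    personality = pd.DataFrame(
        {"bird_id": records["male_id"], "sex": "male",
         "score": scores if scores is not None else np.arange(n, dtype=float)}
    )
    return nestboxes, records, personality


class TestThiessen:
    def test_triangle_all_adjacent(self):
        nestboxes, records, personality = _tables_from_points(
            [(0, 0), (100, 0), (50, 80)]
        )
        net = build_thiessen_network(records, nestboxes, personality, 2001, "male")
        assert count_links(net) == 3 and not net.directed

    def test_near_collinear_row_gives_path(self):
        """Five boxes along a slightly perturbed line: only consecutive
        pairs share a cell boundary."""
        pts = [(100.0 * i, 0.5 * ((-1) ** i)) for i in range(5)]
        nestboxes, records, personality = _tables_from_points(pts)
        net = build_thiessen_network(records, nestboxes, personality, 2001, "male")
        expected = {(f"m{i:02d}", f"m{i+1:02d}") for i in range(4)}
        got = {(min(u, v), max(u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_collinear_points_degenerate(self):
        nestboxes, records, personality = _tables_from_points(
            [(0, 0), (100, 0), (200, 0), (300, 0)]
        )
        with pytest.raises(DegenerateGeometryError):
            build_thiessen_network(records, nestboxes, personality, 2001, "male")

    def test_adjacency_symmetric_and_connected(self, small_dataset):
        ds = small_dataset
        net = build_thiessen_network(ds.records, ds.nestboxes, ds.personality, 2001, "male")
        import networkx as nx

        assert not net.directed
        assert nx.is_connected(net.graph)

    def test_window_clipping_removes_corridor_adjacency(self):
        """Two clusters whose cells would meet in an excluded corridor are
        not adjacent once cells are clipped to the two-part window."""
        from shapely.geometry import MultiPolygon, box

        left = [(10, 10), (10, 90), (60, 50)]
        right = [(940, 10), (940, 90), (890, 50)]
        nestboxes, records, personality = _tables_from_points(left + right)
        window = box(0, 0, 120, 100).union(box(830, 0, 950, 100))
        net = build_thiessen_network(
            records, nestboxes, personality, 2001, "male", window=window
        )
        left_ids = {f"m{i:02d}" for i in range(3)}
        for u, v in net.graph.edges:
            assert (u in left_ids) == (v in left_ids)
        # and each triangle is still internally fully adjacent
        assert count_links(net) == 6

    def test_square_corner_contact_not_adjacent(self):
        """Four boxes on a square: diagonal cells meet only at the centre
        point, which must not count as adjacency."""
        nestboxes, records, personality = _tables_from_points(
            [(0, 0), (100, 0), (0, 100), (100, 100)]
        )
        net = build_thiessen_network(records, nestboxes, personality, 2001, "male")
        got = {frozenset(e) for e in net.graph.edges}
        assert frozenset(("m00", "m03")) not in got
        assert frozenset(("m01", "m02")) not in got
        assert count_links(net) == 4


class TestMeasures:
    def test_isolated_node_strength_zero(self):
        net = make_network([("a", "b", 0.5)], {"a": 1, "b": 2, "c": 3})
        assert node_strength(net, "c") == 0.0

    def test_reciprocal_strength_counts_both_directions(self):
        net = make_network(
            [("a", "b", 0.5), ("b", "a", 0.5), ("a", "c", 0.5), ("c", "a", 0.5)],
            {"a": 1, "b": 2, "c": 3},
        )
        assert node_strength(net, "a") == pytest.approx(2.0)

    def test_strength_matches_edge_list_sum(self):
        rng = np.random.default_rng(5)
        from conftest import random_network

        net = random_network(rng, n_nodes=10)
        for node in net.graph.nodes:
            expected = sum(
                d["weight"] for u, v, d in net.graph.edges(data=True)
                if node in (u, v)
            )
            assert node_strength(net, node) == pytest.approx(expected, rel=1e-12)

    def test_unknown_bird_raises(self):
        net = make_network([("a", "b", 1.0)], {"a": 1, "b": 2})
        with pytest.raises(KeyError):
            node_strength(net, "zzz")

    def test_reciprocity_extremes_and_oracle(self):
        full = make_network([("a", "b", 1), ("b", "a", 1)], {"a": 1, "b": 2})
        assert reciprocity(full) == 1.0
        star = make_network([("a", "b", 1), ("a", "c", 1)], {"a": 1, "b": 2, "c": 3})
        assert reciprocity(star) == 0.0
        rng = np.random.default_rng(9)
        from conftest import random_network

        net = random_network(rng, n_nodes=12)
        pairs = sum(
            1 for u, v in net.graph.edges if net.graph.has_edge(v, u)
        )
        assert reciprocity(net) == pytest.approx(pairs / net.n_edges)

    def test_count_links_conventions(self):
        assert count_links(make_network([], {"a": 1})) == 0
        complete = [
            (u, v, 1.0) for u in "abcd" for v in "abcd" if u != v
        ]
        assert count_links(make_network(complete, {c: 1 for c in "abcd"})) == 12
        tri = make_network(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)],
            {"a": 1, "b": 2, "c": 3}, directed=False,
        )
        assert count_links(tri) == 3
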