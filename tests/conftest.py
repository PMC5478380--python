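import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from nestnet import ScenarioConfig, simulate_dataset
from nestnet.networks import SpatialNetwork


def make_network(edges, scores, directed=True, weighted=True, **meta):
    """Build a SpatialNetwork from an explicit edge list and score dict."""
    g = nx.DiGraph() if directed else nx.Graph()
    for node, score in scores.items():
        attrs = {}
        if score is not None:
            attrs["score"] = float(score)
        g.add_node(node, **attrs)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    meta.setdefault("method", "knn" if directed else "thiessen")
    return SpatialNetwork(graph=g, weighted=weighted, **meta)


def random_network(rng, n_nodes=None, directed=True, weighted=True):
    """A random connected-ish scored network for fuzz/oracle tests."""
    n = n_nodes or rng.integers(3, 13)
    scores = {f"n{i}": float(rng.normal()) for i in range(n)}
    g = nx.DiGraph() if directed else nx.Graph()
    for node, s in scores.items():
        g.add_node(node, score=s)
    edges = set()
    max_pairs = n * (n - 1) // 2 if not directed else n * (n - 1)
    m = min(int(rng.integers(n, n * (n - 1) // 2 + n)), max_pairs)
    while len(edges) < m:
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        if not directed:
            i, j = min(i, j), max(i, j)
        edges.add((int(i), int(j)))
    for i, j in edges:
        w = float(rng.uniform(0.1, 2.0)) if weighted else 1.0
        g.add_edge(f"n{i}", f"n{j}", weight=w)
    return SpatialNetwork(graph=g, weighted=weighted, method="knn" if directed else "thiessen")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest 3-year fully-typed scenario shared by integration tests."""
    cfg = ScenarioConfig(
        n_boxes=120, window=(0, 0, 800, 600), min_spacing=25, n_years=3,
        occupancy=0.5, typed_fraction=1.0, rho=0.6, length_scale=150, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def partial_dataset():
    """Scenario with untyped birds and region labels (Table-1-like)."""
    cfg = ScenarioConfig(
        n_boxes=150, window=(0, 0, 900, 600), min_spacing=25, n_years=4,
        occupancy=0.45, typed_fraction=0.5, rho=0.4, marley_fraction=0.4, seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def line_tables():
    """Four typed male breeders on a line at x = 0, 10, 20, 100."""
    nestboxes = pd.DataFrame(
        {"box_id": ["a", "b", "c", "d"], "x": [0.0, 10.0, 20.0, 100.0],
         "y": [0.0] * 4, "region": ["R"] * 4}
    )
    records = pd.DataFrame(
        {"year": [2001] * 4, "box_id": ["a", "b", "c", "d"],
         "male_id": ["m1", "m2", "m3", "m4"], "female_id": [None] * 4}
    )
    personality = pd.DataFrame(
        {"bird_id": ["m1", "m2", "m3", "m4"], "sex": ["male"] * 4,
         "score": [1.0, 2.0, 3.0, 4.0]}
    )
    return nestboxes, records, personality
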