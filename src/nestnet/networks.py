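"""Spatial proximity networks among territorial breeders.

Two construction rules are provided, both operating on the Euclidean
distances between occupied nestboxes within one breeding season and one
sex:

* **k nearest neighbours** — each breeder is linked to the ``k`` breeders
  of the same sex with the smallest nestbox distance. Because nearest
  neighbourhood is not symmetric the result is a directed graph.
* **Thiessen (Voronoi) polygons** — each occupied box gets the cell of
  points nearer to it than to any other; breeders whose cells share a
  boundary segment of positive length are linked. Undirected.

Weighted networks carry edge weights ``e_ij = 1 / ln(d)``, association
strength declining on the log-distance scale (the scale on which extra-pair
paternity declines with distance in this system); binary networks use unit
weights. Networks can be restricted to personality-typed breeders either
after construction (default — untyped birds still shape the neighbourhood)
or before it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, QhullError
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon, box as shapely_box

from .errors import DegenerateGeometryError, ValidationError

logger = logging.getLogger(__name__)

RESTRICT_ORDERS = ("construct_then_restrict", "restrict_then_construct")

#: Weight clamp: 1/ln(d) is undefined at d=1 and negative below; boxes are
#: metres apart in practice so the clamp is inert on realistic data.
DEFAULT_D_MIN = 2.0


def edge_weight(d: float, d_min: float = DEFAULT_D_MIN) -> float:
    """Association weight 1/ln(max(d, d_min)) for distance ``d`` in metres.

    Strictly decreasing in ``d`` for ``d >= d_min``; requires ``d > 0`` and
    ``d_min > 1`` (ln must be positive).
    """
    if d_min <= 1.0:
        raise ValueError("d_min must exceed 1 metre")
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    if d < d_min:
        logger.warning("distance %.3g m below clamp %.3g m; clamped", d, d_min)
        d = d_min
    return 1.0 / np.log(d)


@dataclass
class SpatialNetwork:
    """A per-year, per-sex breeding proximity network.

    Nodes are bird ids carrying ``box_id``, ``x``, ``y`` and (when known)
    ``score``; edges carry ``weight``. Directedness follows the graph type:
    k-NN networks are directed, Thiessen networks undirected.
    """

    graph: nx.Graph | nx.DiGraph
    year: int | None = None
    sex: str | None = None
    method: str = "knn"
    k: int | None = None
    weighted: bool = True
    restrict_order: str = "construct_then_restrict"

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def metadata(self) -> dict:
        meta = {
            "method": self.method,
            "weighted": self.weighted,
            "directed": self.directed,
        }
        if self.year is not None:
            meta["year"] = int(self.year)
        if self.sex is not None:
            meta["sex"] = self.sex
        if self.k is not None:
            meta["k"] = int(self.k)
        return meta

    def scores(self) -> dict[str, float]:
        return {
            n: d["score"]
            for n, d in self.graph.nodes(data=True)
            if d.get("score") is not None and np.isfinite(d.get("score"))
        }

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Directed edge representation for the assortativity kernel.

        Returns (src_idx, tgt_idx, weights, node_order); undirected graphs
        contribute every edge in both directions.
        """
        nodes = list(self.graph.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        src, tgt, w = [], [], []
        for u, v, data in self.graph.edges(data=True):
            src.append(index[u]); tgt.append(index[v]); w.append(data["weight"])
            if not self.directed:
                src.append(index[v]); tgt.append(index[u]); w.append(data["weight"])
        return (
            np.asarray(src, dtype=np.intp),
            np.asarray(tgt, dtype=np.intp),
            np.asarray(w, dtype=float),
            nodes,
        )

    def score_vector(self) -> np.ndarray:
        return np.array(
            [self.graph.nodes[n].get("score", np.nan) for n in self.graph.nodes],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# node extraction
# ---------------------------------------------------------------------------

def _breeders_for(
    records: pd.DataFrame,
    nestboxes: pd.DataFrame,
    personality: pd.DataFrame,
    year: int,
    sex: str,
    region: str | None,
) -> pd.DataFrame:
    """One row per breeder of ``sex`` in ``year``: bird_id, box_id, x, y, score."""
    id_col = f"{sex}_id"
    if id_col not in records.columns:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    recs = records[records["year"] == year]
    boxes = nestboxes
    if region is not None:
        boxes = nestboxes[nestboxes["region"] == region]
    merged = recs.merge(boxes[["box_id", "x", "y"]], on="box_id", how="inner")
    merged = merged[merged[id_col].notna()]
    scores = personality[personality["sex"] == sex].set_index("bird_id")["score"]
    out = pd.DataFrame(
        {
            "bird_id": merged[id_col].astype(str).to_numpy(),
            "box_id": merged["box_id"].to_numpy(),
            "x": merged["x"].to_numpy(dtype=float),
            "y": merged["y"].to_numpy(dtype=float),
        }
    )
    dup = out["bird_id"][out["bird_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{sex} bird(s) breeding in more than one box in {year}: {sorted(set(dup))}"
        )
    out["score"] = out["bird_id"].map(scores).astype(float)
    return out


def _make_network(
    breeders: pd.DataFrame,
    edges: list[tuple[int, int, float]],
    directed: bool,
    restrict: bool,
    **meta,
) -> SpatialNetwork:
    g = nx.DiGraph() if directed else nx.Graph()
    for row in breeders.itertuples(index=False):
        attrs = {"box_id": row.box_id, "x": row.x, "y": row.y}
        if np.isfinite(row.score):
            attrs["score"] = float(row.score)
        g.add_node(row.bird_id, **attrs)
    ids = breeders["bird_id"].to_numpy()
    for i, j, w in edges:
        g.add_edge(ids[i], ids[j], weight=float(w))
    if restrict:
        untyped = [n for n, d in g.nodes(data=True) if "score" not in d]
        g.remove_nodes_from(untyped)
    return SpatialNetwork(graph=g, **meta)


# ---------------------------------------------------------------------------
# k nearest neighbours
# ---------------------------------------------------------------------------

def build_knn_network(
    records: pd.DataFrame,
    nestboxes: pd.DataFrame,
    personality: pd.DataFrame,
    year: int,
    sex: str,
    k: int = 5,
    weighted: bool = True,
    restrict_order: str = "construct_then_restrict",
    region: str | None = None,
    d_min: float = DEFAULT_D_MIN,
) -> SpatialNetwork:
    """Directed k-nearest-neighbour network for one year and sex.

    Under ``construct_then_restrict`` (default) the k-NN search runs over
    all same-sex breeders and untyped nodes are removed afterwards with
    their incident edges; under ``restrict_then_construct`` the search runs
    among typed breeders only. Distance ties are broken by smaller box_id.
    With fewer than 2 eligible nodes an empty network is returned with a
    warning; with ``k >= n`` every node links to all others.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restrict_order not in RESTRICT_ORDERS:
        raise ValueError(f"restrict_order must be one of {RESTRICT_ORDERS}")
    breeders = _breeders_for(records, nestboxes, personality, year, sex, region)
    if restrict_order == "restrict_then_construct":
        breeders = breeders[np.isfinite(breeders["score"])].reset_index(drop=True)
    meta = dict(
        year=year, sex=sex, method="knn", k=k, weighted=weighted,
        restrict_order=restrict_order,
    )
    n = len(breeders)
    if n < 2:
        logger.warning("knn %s/%s %s: %d eligible node(s); empty network", year, sex, region, n)
        return _make_network(
            breeders, [], directed=True,
            restrict=(restrict_order == "construct_then_restrict"), **meta,
        )
    pts = breeders[["x", "y"]].to_numpy(dtype=float)
    dmat = cdist(pts, pts)
    # tie-break by box_id: secondary sort key is the rank of box_id
    box_rank = np.argsort(np.argsort(breeders["box_id"].to_numpy()))
    edges: list[tuple[int, int, float]] = []
    kk = min(k, n - 1)
    for i in range(n):
        order = np.lexsort((box_rank, dmat[i]))
        order = order[order != i][:kk]
        for j in order:
            d = dmat[i, j]
            w = edge_weight(d, d_min) if weighted else 1.0
            edges.append((i, int(j), w))
    return _make_network(
        breeders, edges, directed=True,
        restrict=(restrict_order == "construct_then_restrict"), **meta,
    )


# ---------------------------------------------------------------------------
# Thiessen polygons
# ---------------------------------------------------------------------------

def _as_window(window, pts: np.ndarray, pad: float = 50.0) -> Polygon:
    if window is None:
        xmin, ymin = pts.min(axis=0) - pad
        xmax, ymax = pts.max(axis=0) + pad
        return shapely_box(xmin, ymin, xmax, ymax)
    from shapely.geometry.base import BaseGeometry

    if isinstance(window, BaseGeometry):
        return window
    xmin, ymin, xmax, ymax = window
    return shapely_box(xmin, ymin, xmax, ymax)


def _voronoi_cells(pts: np.ndarray, window: Polygon) -> tuple[list[Polygon], set[tuple[int, int]]]:
    """Clipped Voronoi cells of ``pts`` plus candidate adjacent index pairs.

    Cells are bounded by mirroring the points across the four sides of the
    window's bounding box before tessellating, then intersecting each cell
    with the window polygon. Candidate pairs are the Voronoi ridges between
    two real points; clipping can only remove adjacency, never add it.
    """
    n = len(pts)
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise DegenerateGeometryError("all points are collinear; no tessellation")
    xmin, ymin, xmax, ymax = window.bounds
    mirrored = [pts]
    for refl in (
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ):
        mirrored.append(refl)
    allpts = np.vstack(mirrored)
    try:
        vor = Voronoi(allpts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"Voronoi tessellation failed (collinear or degenerate points): {exc}"
        ) from exc
    cells: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise DegenerateGeometryError("unbounded cell after mirroring; bad window")
        poly = Polygon(vor.vertices[region])
        cells.append(poly.intersection(window))
    candidates = {
        (min(a, b), max(a, b))
        for a, b in vor.ridge_points
        if a < n and b < n
    }
    return cells, candidates


def build_thiessen_network(
    records: pd.DataFrame,
    nestboxes: pd.DataFrame,
    personality: pd.DataFrame,
    year: int,
    sex: str,
    weighted: bool = True,
    restrict_order: str = "construct_then_restrict",
    region: str | None = None,
    window=None,
    d_min: float = DEFAULT_D_MIN,
) -> SpatialNetwork:
    """Undirected territory-adjacency network from Voronoi cells.

    Cells are clipped to ``window`` (shapely polygon, (xmin, ymin, xmax,
    ymax) tuple, or None for the padded bounding box of the points); two
    breeders are adjacent when their clipped cells share a boundary of
    positive length — point contact, as at the centre of four boxes on a
    square, does not count. Weights are ``edge_weight`` of the
    centre-to-centre distance, or 1 for binary networks.
    """
    if restrict_order not in RESTRICT_ORDERS:
        raise ValueError(f"restrict_order must be one of {RESTRICT_ORDERS}")
    breeders = _breeders_for(records, nestboxes, personality, year, sex, region)
    if restrict_order == "restrict_then_construct":
        breeders = breeders[np.isfinite(breeders["score"])].reset_index(drop=True)
    meta = dict(
        year=year, sex=sex, method="thiessen", k=None, weighted=weighted,
        restrict_order=restrict_order,
    )
    n = len(breeders)
    if n < 3:
        logger.warning("thiessen %s/%s: %d eligible node(s); empty network", year, sex, n)
        return _make_network(
            breeders, [], directed=False,
            restrict=(restrict_order == "construct_then_restrict"), **meta,
        )
    pts = breeders[["x", "y"]].to_numpy(dtype=float)
    win = _as_window(window, pts)
    cells, candidates = _voronoi_cells(pts, win)
    edges: list[tuple[int, int, float]] = []
    for i, j in sorted(candidates):
        if cells[i].is_empty or cells[j].is_empty:
            continue
        shared = cells[i].intersection(cells[j])
        if shared.length > 1e-9:
            d = float(np.hypot(*(pts[i] - pts[j])))
            w = edge_weight(d, d_min) if weighted else 1.0
            edges.append((i, j, w))
    return _make_network(
        breeders, edges, directed=False,
        restrict=(restrict_order == "construct_then_restrict"), **meta,
    )


# ---------------------------------------------------------------------------
# descriptive measures
# ---------------------------------------------------------------------------

def node_strength(network: SpatialNetwork, bird_id: str) -> float:
    """Sum of weights over all incident edges (in + out for directed graphs)."""
    g = network.graph
    if bird_id not in g:
        raise KeyError(f"bird {bird_id!r} not in network")
    if network.directed:
        s = sum(d["weight"] for _, _, d in g.out_edges(bird_id, data=True))
        s += sum(d["weight"] for _, _, d in g.in_edges(bird_id, data=True))
        return float(s)
    return float(sum(d["weight"] for _, _, d in g.edges(bird_id, data=True)))


def reciprocity(network: SpatialNetwork) -> float:
    """Fraction of directed edges whose reverse edge also exists (1.0 if undirected)."""
    if not network.directed:
        return 1.0
    g = network.graph
    m = g.number_of_edges()
    if m == 0:
        return float("nan")
    recip = sum(1 for u, v in g.edges if g.has_edge(v, u))
    return recip / m


def count_links(network: SpatialNetwork) -> int:
    """Directed edge count for k-NN networks; unordered pair count for Thiessen."""
    return network.graph.number_of_edges()
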