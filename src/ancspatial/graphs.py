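"""Spatial neighborhood graphs and weight matrices for areal data.

Three neighborhood definitions are supported, matching the schemes in
common use for administrative (province-level) analyses:

* **queen contiguity** — polygons are neighbors iff their boundaries share
  at least one point (an edge or a single vertex);
* **k-nearest** — each centroid is linked to its k nearest centroids and
  the directed relation is symmetrized by union;
* **distance band** — centroids within a fixed distance are neighbors.

A :class:`SpatialGraph` is converted to a spatial weight matrix ``W``
(zero diagonal by convention) in binary or row-standardized style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialGraph",
    "WeightMatrix",
    "queen_adjacency",
    "knn_graph",
    "distance_band_graph",
    "lattice_graph",
    "weight_matrix",
]


@dataclass
class SpatialGraph:
    """Undirected neighbor structure over labelled areal units."""

    node_ids: list
    edges: set  # of frozenset pairs
    scheme: str = "custom"
    #: per-node metadata, e.g. centroid coordinates
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node labels must be unique")
        nodes = set(self.node_ids)
        clean = set()
        for e in self.edges:
            pair = frozenset(e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not pair <= nodes:
                raise ValueError(f"edge references unknown node(s): {set(pair) - nodes}")
            clean.add(pair)
        self.edges = clean

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def degree(self) -> dict:
        deg = {v: 0 for v in self.node_ids}
        for e in self.edges:
            for v in e:
                deg[v] += 1
        return deg

    def neighbors(self, node) -> list:
        out = []
        for e in self.edges:
            if node in e:
                (other,) = e - {node}
                out.append(other)
        return sorted(out, key=str)

    def isolates(self) -> list:
        deg = self.degree()
        return [v for v in self.node_ids if deg[v] == 0]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency in node_ids order."""
        idx = {v: i for i, v in enumerate(self.node_ids)}
        a = np.zeros((self.n, self.n))
        for e in self.edges:
            i, j = (idx[v] for v in e)
            a[i, j] = a[j, i] = 1.0
        return a

    def components(self) -> list[list]:
        """Connected components as lists of node indices (0-based)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        idx = {v: i for i, v in enumerate(self.node_ids)}
        g.add_edges_from((idx[a], idx[b]) for a, b in map(tuple, self.edges))
        return [sorted(c) for c in nx.connected_components(g)]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass
class WeightMatrix:
    """Spatial weight matrix with zero diagonal.

    ``style="binary"`` gives w_ij in {0, 1}; ``style="row_standardized"``
    divides each row by its sum (zero rows stay zero, so isolated units
    carry no weight).
    """

    w: np.ndarray
    style: str
    node_ids: list | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValueError("weight matrix diagonal must be zero")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


#: Mean Earth radius, km — used by the haversine metric.
EARTH_RADIUS_KM = 6371.0088


def _centroid_arrays(centroids: dict) -> tuple[list, np.ndarray]:
    labels = list(centroids)
    pts = np.asarray([centroids[k] for k in labels], dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must map label -> (x, y)")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("centroid coordinates must be distinct")
    return labels, pts


def _pairwise_distances(pts: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if metric == "haversine":
        # points are (lon, lat) in degrees; distances in km
        lon, lat = np.radians(pts[:, 0]), np.radians(pts[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    raise ValueError("metric must be 'euclidean' or 'haversine'")


def queen_adjacency(polygons: dict) -> SpatialGraph:
    """Queen-contiguity graph from labelled polygons.

    Two units are neighbors iff their boundaries share at least one point
    (shared edge or single shared corner both count).

    Parameters
    ----------
    polygons : dict
        ``unit_id -> shapely Polygon/MultiPolygon`` (or a coordinate
        sequence accepted by ``shapely.Polygon``).
    """
    from shapely import STRtree
    from shapely.geometry import Polygon
    from shapely.geometry.base import BaseGeometry

    if not polygons:
        raise ValueError("no polygons supplied")
    labels = list(polygons)
    geoms = []
    for lab in labels:
        g = polygons[lab]
        if not isinstance(g, BaseGeometry):
            g = Polygon(g)
        if g.is_empty or not g.is_valid:
            raise ValueError(f"invalid or empty polygon for unit {lab!r}")
        geoms.append(g)

    tree = STRtree(geoms)
    edges = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            if int(j) > i:
                edges.add(frozenset((labels[i], labels[int(j)])))
    return SpatialGraph(labels, edges, scheme="queen")


def knn_graph(centroids: dict, k: int = 5, metric: str = "euclidean") -> SpatialGraph:
    """Symmetrized k-nearest-neighbor graph on centroids.

    Each node is linked to its k nearest distinct neighbors (exact ties
    broken by node label order) and the directed relation is symmetrized
    by union, so every node has degree >= k.  ``metric="haversine"``
    treats coordinates as (lon, lat) degrees.
    """
    labels, pts = _centroid_arrays(centroids)
    n = len(labels)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (= {n}), got {k}")
    d = _pairwise_distances(pts, metric)
    np.fill_diagonal(d, np.inf)
    order = np.argsort([str(v) for v in labels], kind="stable")
    edges = set()
    for i in range(n):
        # stable sort on (distance, label rank) makes tie-breaks deterministic
        rank = np.lexsort((order, d[i]))
        for j in rank[:k]:
            edges.add(frozenset((labels[i], labels[int(j)])))
    return SpatialGraph(labels, edges, scheme="knn", meta={"k": k, "centroids": dict(centroids)})


def max_nearest_neighbor_distance(centroids: dict, metric: str = "euclidean") -> float:
    """Smallest distance band that leaves no node isolated."""
    _, pts = _centroid_arrays(centroids)
    d = _pairwise_distances(pts, metric)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


def distance_band_graph(
    centroids: dict, threshold: float | str = "auto", metric: str = "euclidean"
) -> SpatialGraph:
    """Distance-band graph: edge iff 0 < d(i, j) <= threshold.

    ``threshold="auto"`` uses the maximum nearest-neighbor distance,
    which by construction leaves no isolates.  An explicit threshold
    that strands nodes produces a warning listing the isolates, not an
    error.  ``metric="haversine"`` treats coordinates as (lon, lat)
    degrees with distances (and the threshold) in kilometres.
    """
    labels, pts = _centroid_arrays(centroids)
    if threshold == "auto":
        threshold = max_nearest_neighbor_distance(centroids, metric)
    threshold = float(threshold)
    if threshold <= 0:
        raise ValueError("distance threshold must be positive")
    d = _pairwise_distances(pts, metric)
    n = len(labels)
    edges = {
        frozenset((labels[i], labels[j]))
        for i in range(n) for j in range(i + 1, n)
        if d[i, j] <= threshold
    }
    graph = SpatialGraph(
        labels, edges, scheme="distance_band",
        meta={"threshold": threshold, "centroids": dict(centroids)},
    )
    iso = graph.isolates()
    if iso:
        warnings.warn(
            f"distance band {threshold} leaves {len(iso)} isolated unit(s): {iso[:10]}",
            stacklevel=2,
        )
    return graph


def lattice_graph(rows: int, cols: int, contiguity: str = "rook") -> SpatialGraph:
    """Regular rows x cols grid with rook or queen contiguity.

    Node labels are ``"r{i}c{j}"``; cell (i, j) occupies the unit square
    with lower-left corner (j, -i), so centroid/polygon exports agree
    with the graph.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if contiguity not in ("rook", "queen"):
        raise ValueError("contiguity must be 'rook' or 'queen'")
    lab = lambda i, j: f"r{i}c{j}"
    steps = [(0, 1), (1, 0)]
    if contiguity == "queen":
        steps += [(1, 1), (1, -1)]
    edges = set()
    for i in range(rows):
        for j in range(cols):
            for di, dj in steps:
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols:
                    edges.add(frozenset((lab(i, j), lab(ni, nj))))
    labels = [lab(i, j) for i in range(rows) for j in range(cols)]
    centroids = {lab(i, j): (j + 0.5, -i - 0.5) for i in range(rows) for j in range(cols)}
    return SpatialGraph(
        labels, edges, scheme="custom",
        meta={"rows": rows, "cols": cols, "contiguity": contiguity, "centroids": centroids},
    )


def weight_matrix(graph: SpatialGraph, style: str = "binary") -> WeightMatrix:
    """Spatial weight matrix from a neighborhood graph.

    Binary style gives the symmetric 0/1 adjacency; row standardization
    divides each row by its sum (rows of isolated units stay zero).
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    if style not in ("binary", "row_standardized"):
        raise ValueError("style must be 'binary' or 'row_standardized'")
    w = graph.adjacency()
    if style == "row_standardized":
        sums = w.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        w[nz] = w[nz] / sums[nz]
    return WeightMatrix(w, style=style, node_ids=list(graph.node_ids))
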