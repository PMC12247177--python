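"""Readers and writers binding the pipeline to plain-text formats.

CSV for tables, GeoJSON for polygon geometry, a simple text adjacency
format (``id: id1,id2,...``) for neighbor lists, JSON for results and
simulation truth.  No binary formats are produced or consumed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from ancspatial.graphs import SpatialGraph
from ancspatial.regions import RegionTable

__all__ = [
    "read_region_csv",
    "write_region_csv",
    "read_geojson",
    "write_geojson",
    "read_adjacency",
    "write_adjacency",
    "read_centroid_csv",
    "write_results",
]


def read_region_csv(path) -> RegionTable:
    """Read a region table; requires ``unit_id,sample,events`` columns."""
    df = pd.read_csv(path)
    missing = [c for c in ("unit_id", "sample", "events") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["unit_id"] = df["unit_id"].astype(str)
    return RegionTable(df)


def write_region_csv(table: RegionTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_geojson(path) -> dict:
    """Polygons from a GeoJSON FeatureCollection, keyed by unit_id.

    Each feature must be a Polygon or MultiPolygon and carry a
    ``unit_id`` property.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = {}
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        uid = props.get("unit_id")
        if uid is None:
            raise ValueError(f"{path}: feature #{k} lacks a unit_id property")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"{path}: unit {uid!r} is a {geom.geom_type}, not a polygon")
        if uid in out:
            raise ValueError(f"{path}: duplicate unit_id {uid!r}")
        out[str(uid)] = geom
    if not out:
        raise ValueError(f"{path}: no features")
    return out


def write_geojson(polygons: dict, path) -> None:
    """Write labelled polygons as a GeoJSON FeatureCollection."""
    from shapely.geometry import mapping

    features = [
        {
            "type": "Feature",
            "properties": {"unit_id": str(uid)},
            "geometry": mapping(geom),
        }
        for uid, geom in polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_adjacency(path) -> SpatialGraph:
    """Neighbor list, one node per line: ``id: id1,id2,...``.

    The relation is symmetrized on read; one-sided entries generate a
    warning naming the pair.  A line with no neighbors (``id:``)
    declares an isolated node.
    """
    nodes: list = []
    listed: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'id: id1,id2,...'")
            head, _, tail = line.partition(":")
            head = head.strip()
            if head in listed:
                raise ValueError(f"{path}:{lineno}: duplicate node {head!r}")
            nodes.append(head)
            listed[head] = {t.strip() for t in tail.split(",") if t.strip()}
    known = set(nodes)
    edges = set()
    for a, nbrs in listed.items():
        for b in nbrs:
            if b not in known:
                nodes.append(b)
                known.add(b)
                listed.setdefault(b, set())
            if a == b:
                raise ValueError(f"{path}: self-loop on {a!r}")
            if a not in listed.get(b, set()):
                warnings.warn(
                    f"adjacency entry {a!r}: {b!r} not reciprocated; symmetrizing",
                    stacklevel=2,
                )
            edges.add(frozenset((a, b)))
    return SpatialGraph(nodes, edges, scheme="custom")


def write_adjacency(graph: SpatialGraph, path) -> None:
    with open(path, "w") as fh:
        for node in graph.node_ids:
            fh.write(f"{node}: {','.join(map(str, graph.neighbors(node)))}\n")


def read_centroid_csv(path) -> dict:
    """Centroids from a ``unit_id,x,y`` CSV, as label -> (x, y)."""
    df = pd.read_csv(path)
    missing = [c for c in ("unit_id", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["unit_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate unit_id values")
    return {
        str(r.unit_id): (float(r.x), float(r.y)) for r in df.itertuples(index=False)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(objects: dict, outdir, force: bool = False) -> dict:
    """Write a dict of result objects and a manifest of file hashes.

    ``objects`` maps file names to DataFrames (written as CSV), dicts or
    lists (JSON) or plain strings.  Refuses to overwrite existing files
    unless ``force``.  Returns the manifest ``{filename: sha256}``, also
    written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, obj in objects.items():
        target = outdir / name
        if target.exists() and not force:
            raise FileExistsError(f"{target} exists; pass force=True to overwrite")
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(target, index=False)
        elif isinstance(obj, (dict, list)):
            target.write_text(json.dumps(obj, indent=2, default=_jsonify))
        else:
            target.write_text(str(obj))
        manifest[name] = _sha256(target)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
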