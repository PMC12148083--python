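"""GeoJSON vector I/O: start-region polygons, target-site points, rivers."""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .cost_surface import RiverSegment

__all__ = [
    "read_region",
    "read_sites",
    "read_rivers",
    "write_region",
    "write_sites",
    "write_rivers",
]


def _features(doc: dict) -> list[dict]:
    if doc.get("type") == "FeatureCollection":
        return doc["features"]
    if doc.get("type") == "Feature":
        return [doc]
    return [{"type": "Feature", "geometry": doc, "properties": {}}]


def read_region(path: str | Path) -> BaseGeometry:
    """Union of all polygon features in a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in _features(doc)]
    if not geoms:
        raise ValueError(f"no geometry in {path}")
    return unary_union(geoms)


def read_sites(path: str | Path) -> list[tuple[float, float]]:
    """Point coordinates of all point features in a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    points = []
    for f in _features(doc):
        geom = shape(f["geometry"])
        if geom.geom_type == "Point":
            points.append((geom.x, geom.y))
        elif geom.geom_type == "MultiPoint":
            points.extend((p.x, p.y) for p in geom.geoms)
        else:
            raise ValueError(f"expected point features in {path}, got {geom.geom_type}")
    if not points:
        raise ValueError(f"no point features in {path}")
    return points


def read_rivers(path: str | Path) -> list[RiverSegment]:
    """LineString features with a ``discharge_m3s`` property."""
    doc = json.loads(Path(path).read_text())
    rivers = []
    for f in _features(doc):
        geom = shape(f["geometry"])
        if geom.geom_type != "LineString":
            raise ValueError(f"expected LineString features in {path}, got {geom.geom_type}")
        props = f.get("properties") or {}
        if "discharge_m3s" not in props:
            raise ValueError(f"river feature in {path} lacks a discharge_m3s property")
        rivers.append(
            RiverSegment(xy=[(x, y) for x, y in geom.coords], discharge_m3s=float(props["discharge_m3s"]))
        )
    return rivers


def _write_fc(features: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path


def write_region(geom: BaseGeometry, path: str | Path) -> Path:
    return _write_fc([{"type": "Feature", "geometry": mapping(geom), "properties": {}}], path)


def write_sites(points: list[tuple[float, float]], path: str | Path) -> Path:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {},
        }
        for x, y in points
    ]
    return _write_fc(feats, path)


def write_rivers(rivers: list[RiverSegment], path: str | Path) -> Path:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [[x, y] for x, y in r.xy]},
            "properties": {"discharge_m3s": r.discharge_m3s},
        }
        for r in rivers
    ]
    return _write_fc(feats, path)
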