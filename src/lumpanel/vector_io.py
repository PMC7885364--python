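"""GeoJSON feature IO with planar-CRS validation.

All distances in the pipeline are metric, so inputs must use a projected
planar CRS in meters (the Dutch national data use RD New, EPSG:28992).
GeoJSON files are treated as plain geometry containers with a declared CRS
carried in the (legacy) top-level ``crs`` member; files whose coordinates
look like longitude/latitude degrees are refused.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from lumpanel.errors import CRSError

DEFAULT_CRS = "EPSG:28992"


def _looks_geographic(geoms: Sequence[BaseGeometry]) -> bool:
    """Heuristic: every coordinate inside the lon/lat envelope."""
    if not geoms:
        return False
    for g in geoms:
        minx, miny, maxx, maxy = g.bounds
        if not (-360.0 <= minx <= 360.0 and -360.0 <= maxx <= 360.0):
            return False
        if not (-90.0 <= miny <= 90.0 and -90.0 <= maxy <= 90.0):
            return False
    return True


def validate_planar(geoms: Sequence[BaseGeometry], crs: str | None) -> None:
    """Reject geographic coordinates; require a declared planar CRS.

    Raises
    ------
    CRSError
        If ``crs`` is missing, names a geographic system, or the coordinates
        all fall inside the degree envelope (a strong sign of lon/lat data).
    """
    if crs is None:
        raise CRSError(
            "no CRS declared; inputs must use a projected planar CRS in meters "
            "(e.g. EPSG:28992)"
        )
    if str(crs).upper() in {"EPSG:4326", "WGS84", "CRS84", "OGC:CRS84"}:
        raise CRSError(f"geographic CRS {crs!r} rejected; reproject to meters first")
    if _looks_geographic(geoms):
        raise CRSError(
            "coordinates fall inside the longitude/latitude envelope; "
            "inputs appear to be geographic degrees, not planar meters"
        )


def read_features(path: str | Path) -> tuple[list[BaseGeometry], list[dict], str]:
    """Read a GeoJSON FeatureCollection.

    Returns (geometries, properties, crs) after planar validation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise CRSError(f"{path}: not a GeoJSON FeatureCollection")
    crs = None
    crs_member = doc.get("crs")
    if isinstance(crs_member, dict):
        crs = crs_member.get("properties", {}).get("name")
    elif isinstance(crs_member, str):
        crs = crs_member
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [dict(f.get("properties") or {}) for f in doc["features"]]
    validate_planar(geoms, crs)
    return geoms, props, crs


def write_features(
    path: str | Path,
    geoms: Iterable[BaseGeometry],
    props: Iterable[dict],
    crs: str = DEFAULT_CRS,
) -> None:
    """Write a GeoJSON FeatureCollection with a declared planar CRS."""
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, props)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)
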