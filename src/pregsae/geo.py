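"""Polygon containers and GeoJSON round-tripping.

Areas are kept as an ordered mapping ``area_id -> shapely Polygon`` in a
planar miles frame.  GeoJSON files written here carry plain x/y coordinates
in miles (documented in the file's top-level ``crs_note`` member); real
deployments would project geographic coordinates before use.
"""

from __future__ import annotations

import json
from typing import Dict

from shapely.geometry import Polygon, shape, mapping

from .errors import InvalidArgumentError

Polygons = Dict[str, Polygon]


def polygon_areas(polygons: Polygons) -> Dict[str, float]:
    """Area of each polygon in square miles."""
    return {aid: poly.area for aid, poly in polygons.items()}


def total_bounds(polygons: Polygons):
    """(minx, miny, maxx, maxy) of the union of all polygons."""
    import numpy as np

    bounds = [p.bounds for p in polygons.values()]
    arr = np.asarray(bounds)
    return float(arr[:, 0].min()), float(arr[:, 1].min()), float(arr[:, 2].max()), float(arr[:, 3].max())


def polygons_to_geojson(polygons: Polygons, properties: dict | None = None) -> dict:
    """Build a GeoJSON FeatureCollection; extra per-area properties optional."""
    features = []
    for aid, poly in polygons.items():
        props = {"area_id": aid, "area_sqmi": poly.area}
        if properties and aid in properties:
            props.update(properties[aid])
        features.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    return {
        "type": "FeatureCollection",
        "crs_note": "planar coordinates in miles (x=longitude column, y=latitude column)",
        "features": features,
    }


def polygons_from_geojson(obj: dict) -> Polygons:
    if obj.get("type") != "FeatureCollection":
        raise InvalidArgumentError("expected a GeoJSON FeatureCollection")
    polygons: Polygons = {}
    for feat in obj["features"]:
        aid = str(feat["properties"]["area_id"])
        polygons[aid] = shape(feat["geometry"])
    return dict(sorted(polygons.items()))


def write_polygons(polygons: Polygons, path, properties: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(polygons_to_geojson(polygons, properties), fh, indent=1)


def read_polygons(path) -> Polygons:
    with open(path) as fh:
        return polygons_from_geojson(json.load(fh))
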