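"""Land / ocean tests used to trim utilisation distributions.

A land mask is just a vectorised predicate ``is_land(lon, lat) -> bool``.
Two sources are supported: shapely polygon layers (e.g. Natural Earth
land, read from GeoJSON) and boolean per-cell masks on the global grid
(the synthetic worlds' native representation).
"""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .grids import GlobalGrid


def from_polygons(geoms) -> "callable":
    """Predicate from an iterable of shapely geometries (point-in-polygon
    on cell centres)."""
    union = unary_union(list(geoms))
    shapely.prepare(union)

    def is_land(lon, lat):
        return shapely.contains_xy(union, np.asarray(lon), np.asarray(lat))

    return is_land


def from_grid_mask(mask: np.ndarray, grid: GlobalGrid | None = None) -> "callable":
    """Predicate from a boolean (nlat, nlon) land mask: a point is land iff
    the cell containing it is land."""
    grid = grid or GlobalGrid()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")

    def is_land(lon, lat):
        ilat, ilon = grid.cell_index(np.asarray(lon), np.asarray(lat))
        return mask[ilat, ilon]

    return is_land


def ocean_everywhere(lon, lat):
    """Trivial mask for worlds without land."""
    return np.zeros(np.shape(np.asarray(lon)), dtype=bool)


def read_geojson_polygons(path) -> list:
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    return [shape(f["geometry"]) for f in feats]


def write_geojson_polygons(geoms, path, properties=None) -> None:
    properties = properties or [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
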