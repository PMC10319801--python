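"""Attribution of exposure risk to maritime jurisdictions.

Each 1-degree cell is assigned to the first polygon (file order) whose
interior-or-boundary contains the cell centre; cells in no polygon belong
to the high seas. Exposure in a joint regime or overlapping claim is split
evenly among its sovereigns. Assignment by cell centre is a deliberate,
resolution-limited approximation: a cell straddling a boundary is credited
wholly to the polygon holding its centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grids import GlobalDensityGrid, GlobalGrid

HIGH_SEAS = "High seas"
CATEGORIES = ("EEZ", "theoretical-EEZ", "joint-regime")


@dataclass
class JurisdictionPolygon:
    name: str
    sovereigns: list[str]
    category: str
    geometry: "shapely.Geometry"

    def __post_init__(self):
        if not self.sovereigns:
            raise ValueError(f"jurisdiction {self.name!r} has no sovereigns")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown jurisdiction category {self.category!r}")
        if not self.geometry.is_valid:
            raise ValueError(f"invalid polygon for jurisdiction {self.name!r}")


@dataclass
class JurisdictionLayer:
    polygons: list[JurisdictionPolygon]

    @classmethod
    def from_geojson(cls, path) -> "JurisdictionLayer":
        with open(path) as fh:
            gj = json.load(fh)
        polys = []
        for feat in gj["features"]:
            props = feat["properties"]
            sov = props["sovereigns"]
            if isinstance(sov, str):
                sov = [s.strip() for s in sov.split(";") if s.strip()]
            polys.append(
                JurisdictionPolygon(
                    name=props["name"],
                    sovereigns=sov,
                    category=props["category"],
                    geometry=shape(feat["geometry"]),
                )
            )
        return cls(polys)

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {
                    "name": p.name,
                    "sovereigns": ";".join(p.sovereigns),
                    "category": p.category,
                },
            }
            for p in self.polygons
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def assign_cells(layer: JurisdictionLayer, grid: GlobalGrid | None = None) -> np.ndarray:
    """Integer polygon index per cell (-1 = high seas), by centre-point
    inclusion; boundary ties go to the first polygon in file order."""
    grid = grid or GlobalGrid()
    lat2d, lon2d = grid.cell_centers()
    assignment = np.full(grid.shape, -1, dtype=int)
    unassigned = np.ones(grid.shape, dtype=bool)
    for i, poly in enumerate(layer.polygons):
        geom = poly.geometry
        shapely.prepare(geom)
        inside = shapely.intersects_xy(geom, lon2d, lat2d)
        take = inside & unassigned
        assignment[take] = i
        unassigned &= ~take
    return assignment


def partition_score(
    exposure: GlobalDensityGrid,
    assignment: np.ndarray,
    layer: JurisdictionLayer,
) -> pd.DataFrame:
    """Credit each cell's exposure to its jurisdiction, splitting joint
    regimes evenly among sovereigns.

    Returns one row per (jurisdiction, sovereign) with the absolute score
    share and the fraction of the total; fractions sum to one.
    """
    values = np.where(np.isnan(exposure.values), 0.0, exposure.values)
    total = values.sum()
    rows = []
    for i, poly in enumerate(layer.polygons):
        score = float(values[assignment == i].sum())
        for sov in poly.sovereigns:
            rows.append(
                {
                    "jurisdiction": poly.name,
                    "category": poly.category,
                    "sovereign": sov,
                    "score_share": score / len(poly.sovereigns),
                }
            )
    rows.append(
        {
            "jurisdiction": HIGH_SEAS,
            "category": HIGH_SEAS,
            "sovereign": "",
            "score_share": float(values[assignment == -1].sum()),
        }
    )
    df = pd.DataFrame(rows)
    df["fraction"] = df["score_share"] / total if total > 0 else 0.0
    return df


def breeding_country_linkage(
    population_shares: dict[str, pd.DataFrame],
    breeding_countries: dict[str, str],
) -> pd.DataFrame:
    """Per population: fraction of exposure inside vs outside the breeding
    country's own EEZ(s), and whether the own-EEZ share is the maximum
    across all jurisdictions (high seas included)."""
    rows = []
    for pop, shares in population_shares.items():
        country = breeding_countries.get(pop, "")
        own = shares.loc[
            (shares["sovereign"] == country) & (shares["category"] != HIGH_SEAS),
            "fraction",
        ].sum()
        by_jurisdiction = shares.groupby("jurisdiction")["fraction"].sum()
        rows.append(
            {
                "population_id": pop,
                "breeding_country": country,
                "own_eez_fraction": float(own),
                "outside_fraction": float(1.0 - own),
                "own_eez_is_max": bool(own >= by_jurisdiction.max() - 1e-12),
            }
        )
    return pd.DataFrame(rows)
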