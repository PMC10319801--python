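"""Global 1x1-degree grid containers shared by the petrel-density and
plastic-density halves of the analysis.

A :class:`GlobalGrid` defines the cell layout: cells are half-open
[i, i+1) degree squares in both axes, indexed by their south-west corner,
row 0 at 90S and column 0 at 180W. A :class:`GlobalDensityGrid` carries one
value per cell with NaN marking missing cells, plus a flag recording
whether it has been normalised to unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .geo import CoordinateError, normalize_lon

NORMALIZE_TOL = 1e-9


class NormalizationError(ValueError):
    """Raised when a grid cannot be normalised (all missing or zero)."""


@dataclass(frozen=True)
class GlobalGrid:
    """Layout of the global lat/lon grid (default 1x1 degree)."""

    cell_deg: float = 1.0

    @property
    def nlat(self) -> int:
        return round(180.0 / self.cell_deg)

    @property
    def nlon(self) -> int:
        return round(360.0 / self.cell_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def ncells(self) -> int:
        return self.nlat * self.nlon

    def cell_index(self, lon, lat):
        """(lon, lat) -> (ilat, ilon) of the containing cell.

        Cells are half-open in both axes; lat = 90 is assigned to the
        northernmost row so the pole does not fall off the grid.
        """
        lon = normalize_lon(lon)
        lat = np.asarray(lat, dtype=float)
        if np.any(lat < -90.0) or np.any(lat > 90.0):
            raise CoordinateError("latitude outside [-90, 90]")
        ilat = np.minimum(
            np.floor((lat + 90.0) / self.cell_deg).astype(int), self.nlat - 1
        )
        ilon = np.minimum(
            np.floor((lon + 180.0) / self.cell_deg).astype(int), self.nlon - 1
        )
        return ilat, ilon

    def cell_centers(self):
        """(lat2d, lon2d) arrays of cell-centre coordinates."""
        lat = -90.0 + self.cell_deg * (np.arange(self.nlat) + 0.5)
        lon = -180.0 + self.cell_deg * (np.arange(self.nlon) + 0.5)
        lon2d, lat2d = np.meshgrid(lon, lat)
        return lat2d, lon2d

    def center_coords(self):
        """1-D centre coordinates (lat, lon) for labelling."""
        lat = -90.0 + self.cell_deg * (np.arange(self.nlat) + 0.5)
        lon = -180.0 + self.cell_deg * (np.arange(self.nlon) + 0.5)
        return lat, lon


@dataclass
class GlobalDensityGrid:
    """Per-cell values on a :class:`GlobalGrid`; NaN marks missing cells."""

    values: np.ndarray
    grid: GlobalGrid = field(default_factory=GlobalGrid)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: GlobalGrid | None = None) -> "GlobalDensityGrid":
        grid = grid or GlobalGrid()
        return cls(np.zeros(grid.shape), grid)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def total(self) -> float:
        return float(np.nansum(self.values))

    def copy(self) -> "GlobalDensityGrid":
        return GlobalDensityGrid(self.values.copy(), self.grid, self.normalized)

    def normalize(self) -> "GlobalDensityGrid":
        """Divide non-missing values by their total so the grid sums to one.

        Missing cells stay missing; idempotent up to floating error.
        """
        total = self.total()
        if not np.isfinite(total) or total <= 0.0:
            raise NormalizationError("grid has no positive mass to normalise")
        out = self.values / total
        return GlobalDensityGrid(out, self.grid, normalized=True)

    # --- I/O ---------------------------------------------------------------

    def to_dataarray(self, name: str = "density") -> xr.DataArray:
        lat, lon = self.grid.center_coords()
        return xr.DataArray(
            self.values,
            coords={"lat": lat, "lon": lon},
            dims=("lat", "lon"),
            name=name,
            attrs={"normalized": int(self.normalized)},
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "GlobalDensityGrid":
        cell = float(abs(da["lat"].values[1] - da["lat"].values[0]))
        grid = GlobalGrid(cell_deg=cell)
        values = np.asarray(da.values, dtype=float)
        return cls(values, grid, normalized=bool(da.attrs.get("normalized", 0)))

    def to_netcdf(self, path, name: str = "density") -> None:
        self.to_dataarray(name).to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, name: str = "density") -> "GlobalDensityGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataarray(ds[name].load())

    def to_csv(self, path) -> None:
        """Long-form (lon, lat, density) table of non-missing cells."""
        lat2d, lon2d = self.grid.cell_centers()
        keep = ~self.missing
        pd.DataFrame(
            {"lon": lon2d[keep], "lat": lat2d[keep], "density": self.values[keep]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell_deg: float = 1.0) -> "GlobalDensityGrid":
        df = pd.read_csv(path)
        grid = GlobalGrid(cell_deg=cell_deg)
        values = np.full(grid.shape, np.nan)
        ilat, ilon = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
        values[ilat, ilon] = df["density"].to_numpy(dtype=float)
        return cls(values, grid)


def zero_missing(grid: GlobalDensityGrid) -> GlobalDensityGrid:
    """Replace missing cells by zero (for summations over grids)."""
    out = grid.values.copy()
    out[np.isnan(out)] = 0.0
    return replace(grid.copy(), values=out)
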