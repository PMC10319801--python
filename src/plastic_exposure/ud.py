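"""Monthly kernel utilisation distributions (UDs).

For each population-month the pooled at-sea locations are projected to a
Lambert azimuthal equal-area plane centred on their spherical centroid,
smoothed with a fixed-bandwidth bivariate Gaussian kernel (200 km, the
magnitude of geolocator position error) on a 10 km grid, clipped to the
95% isopleth (the smallest set of highest-density cells holding 95% of the
mass), trimmed over land, and aggregated back onto the global 1x1-degree
grid by fine-cell-centre membership.

Masses are stored unnormalised; normalisation to unit sum happens once, at
exposure time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import AzimuthalEqualArea, spherical_centroid
from .grids import GlobalDensityGrid, GlobalGrid

KDE_BANDWIDTH_KM = 200.0
KDE_CELL_KM = 10.0
ISOPLETH_LEVEL = 0.95
MIN_LOCATIONS_PER_MONTH = 5


@dataclass
class FineUD:
    """A planar kernel density surface for one population-month.

    ``mass`` holds probability mass per cell (density x cell area) on a
    grid whose cell (iy, ix) has centre (x0 + (ix+0.5)*cell_km,
    y0 + (iy+0.5)*cell_km) in projected km coordinates.
    """

    population_id: str
    month: int
    projection: AzimuthalEqualArea
    cell_km: float
    x0: float
    y0: float
    mass: np.ndarray  # (ny, nx)
    isopleth_mask: np.ndarray | None = field(default=None)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def cell_centers_xy(self):
        ny, nx = self.mass.shape
        x = self.x0 + self.cell_km * (np.arange(nx) + 0.5)
        y = self.y0 + self.cell_km * (np.arange(ny) + 0.5)
        return np.meshgrid(x, y)

    def cell_centers_lonlat(self):
        x2d, y2d = self.cell_centers_xy()
        return self.projection.inverse(x2d, y2d)


def month_filter(
    points: pd.DataFrame, n_min: int = MIN_LOCATIONS_PER_MONTH
) -> dict[int, pd.DataFrame]:
    """Pool locations by calendar month (across individuals and years) and
    drop months with fewer than ``n_min`` locations."""
    if len(points) == 0:
        return {}
    month = pd.to_datetime(points["date_time"], utc=True).dt.month
    return {
        int(m): sub.reset_index(drop=True)
        for m, sub in points.groupby(month.to_numpy())
        if len(sub) >= n_min
    }


def kernel_ud(
    points: pd.DataFrame,
    projection: AzimuthalEqualArea | None = None,
    h: float = KDE_BANDWIDTH_KM,
    cell_km: float = KDE_CELL_KM,
    margin_bandwidths: float = 3.0,
    population_id: str = "",
    month: int = 0,
) -> FineUD:
    """Fixed-bandwidth bivariate Gaussian KDE evaluated at cell centres.

    The kernel is separable, so the exact point-to-cell evaluation is the
    outer product of one-dimensional Gaussian matrices (no binning
    approximation). The grid extent covers all points plus a margin of
    ``margin_bandwidths`` x h, which truncates < 1e-3 of each kernel's
    mass. Density is converted to per-cell mass via the (equal-area) cell
    area, so total mass is slightly below one by the truncated tails.
    """
    lon = points["longitude"].to_numpy(dtype=float)
    lat = points["latitude"].to_numpy(dtype=float)
    if projection is None:
        projection = AzimuthalEqualArea(*spherical_centroid(lon, lat))
    px, py = projection.forward(lon, lat)
    px = np.atleast_1d(px)
    py = np.atleast_1d(py)
    margin = margin_bandwidths * h
    x0 = np.floor((px.min() - margin) / cell_km) * cell_km
    y0 = np.floor((py.min() - margin) / cell_km) * cell_km
    nx = int(np.ceil((px.max() + margin - x0) / cell_km))
    ny = int(np.ceil((py.max() + margin - y0) / cell_km))
    xc = x0 + cell_km * (np.arange(nx) + 0.5)
    yc = y0 + cell_km * (np.arange(ny) + 0.5)
    # separable Gaussian: density = Gy^T Gx / (n * 2*pi*h^2)
    gx = np.exp(-0.5 * ((xc[None, :] - px[:, None]) / h) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - py[:, None]) / h) ** 2)
    density = (gy.T @ gx) / (len(px) * 2.0 * np.pi * h * h)
    mass = density * cell_km * cell_km
    return FineUD(
        population_id=population_id,
        month=month,
        projection=projection,
        cell_km=cell_km,
        x0=x0,
        y0=y0,
        mass=mass,
    )


def apply_isopleth(ud: FineUD, level: float = ISOPLETH_LEVEL) -> FineUD:
    """Clip to the smallest set of highest-density cells holding ``level``
    of the total mass; interior densities are retained, not flattened.

    Ties at the boundary are broken by stable cell order (row-major index)
    within equal density, via a stable descending sort.
    """
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    target = level * flat.sum()
    k = int(np.searchsorted(csum, target)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.mass.shape)
    clipped = np.where(mask, ud.mass, 0.0)
    return FineUD(
        ud.population_id, ud.month, ud.projection, ud.cell_km, ud.x0, ud.y0,
        clipped, isopleth_mask=mask,
    )


def trim_land(ud: FineUD, is_land) -> FineUD:
    """Zero the mass of cells whose centre lies on land.

    ``is_land`` is a callable mapping (lon, lat) arrays to a boolean array
    (see :mod:`plastic_exposure.landmask`)."""
    lon, lat = ud.cell_centers_lonlat()
    land = np.asarray(is_land(lon, lat), dtype=bool)
    trimmed = np.where(land, 0.0, ud.mass)
    return FineUD(
        ud.population_id, ud.month, ud.projection, ud.cell_km, ud.x0, ud.y0,
        trimmed, isopleth_mask=ud.isopleth_mask,
    )


def aggregate_to_global(ud: FineUD, grid: GlobalGrid | None = None) -> GlobalDensityGrid:
    """Back-project the fine UD and accumulate each fine cell's mass into
    the 1-degree cell containing its centre. Mass is conserved exactly
    (floating-point summation aside)."""
    grid = grid or GlobalGrid()
    lon, lat = ud.cell_centers_lonlat()
    ilat, ilon = grid.cell_index(np.asarray(lon).ravel(), np.asarray(lat).ravel())
    values = np.zeros(grid.shape)
    np.add.at(values, (ilat, ilon), ud.mass.ravel())
    return GlobalDensityGrid(values, grid)


def monthly_global_ud(
    points: pd.DataFrame,
    is_land,
    h: float = KDE_BANDWIDTH_KM,
    cell_km: float = KDE_CELL_KM,
    level: float = ISOPLETH_LEVEL,
    grid: GlobalGrid | None = None,
    population_id: str = "",
    month: int = 0,
) -> GlobalDensityGrid:
    """Full UD chain for one population-month: centroid projection -> KDE
    -> 95% isopleth -> land trim -> aggregate to the global grid."""
    fine = kernel_ud(
        points, h=h, cell_km=cell_km, population_id=population_id, month=month
    )
    fine = apply_isopleth(fine, level)
    fine = trim_land(fine, is_land)
    return aggregate_to_global(fine, grid)
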