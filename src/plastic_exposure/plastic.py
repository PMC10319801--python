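"""Combining gridded plastic-density model outputs into one layer.

Floating-plastic densities from independent Lagrangian transport models
vary on a log scale, so the per-cell combination is the geometric mean:
with all three models present, gm of three; with one missing, gm of the
remaining two; with two missing, the single available estimate; with none,
the combined cell is missing. A zero density is treated as an exact zero
("no plastic predicted"), making the geometric mean zero wherever any
contributing model predicts zero.

Model grids are natively centred at 180 degrees east; they are reoriented
to the [-180, 180) global grid at read time. The 0-1 degrees west column
is known-bad in the source models and is imputed from the mean of the
three columns either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GlobalDensityGrid, GlobalGrid


@dataclass
class PlasticModelLayer:
    """One model's 1x1-degree density grid (pieces per km^2)."""

    model_name: str
    grid: GlobalDensityGrid

    def __post_init__(self):
        vals = self.grid.values
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError(f"negative densities in model {self.model_name!r}")


@dataclass
class CombinedPlasticLayer:
    grid: GlobalDensityGrid
    n_models: np.ndarray  # contributing-model count per cell, 0..3
    imputed: np.ndarray  # bool per cell


def reorient_from_180(values: np.ndarray) -> np.ndarray:
    """Shift a grid stored with the prime meridian at the array edge
    (180E-centred) onto the [-180, 180) layout."""
    return np.roll(values, values.shape[1] // 2, axis=1)


def combine_models(layers: list[PlasticModelLayer]) -> CombinedPlasticLayer:
    """Per-cell geometric mean across models with missing-value fallback."""
    if len(layers) != 3:
        raise ValueError("expected exactly three model layers")
    grid = layers[0].grid.grid
    for layer in layers[1:]:
        if layer.grid.grid != grid:
            raise ValueError("model layers are not co-registered")
    stack = np.stack([layer.grid.values for layer in layers])  # (3, nlat, nlon)
    present = ~np.isnan(stack)
    n_models = present.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(present & (stack > 0), np.log(np.where(stack > 0, stack, 1.0)), 0.0)
        gm = np.exp(np.where(n_models > 0, logs.sum(axis=0) / np.maximum(n_models, 1), np.nan))
    # any contributing zero forces the geometric mean to zero
    any_zero = (present & (stack == 0)).any(axis=0)
    gm = np.where(any_zero, 0.0, gm)
    gm = np.where(n_models == 0, np.nan, gm)
    return CombinedPlasticLayer(
        grid=GlobalDensityGrid(gm, grid),
        n_models=n_models,
        imputed=np.zeros(grid.shape, dtype=bool),
    )


def impute_band(
    layer: CombinedPlasticLayer, band_lon: float = -1.0, n_neighbors: int = 3
) -> CombinedPlasticLayer:
    """Impute the known-bad one-degree column (default 0-1W) row-wise from
    the arithmetic mean of the non-missing values among its six neighbour
    columns; missing if all neighbours are missing.

    The bad column sat at the edge of the models' native 180-centred
    arrays, so its neighbours "east" are the columns just west of the
    antimeridian (177-180E), while its neighbours west are the ordinary
    adjacent columns (1-4W).
    """
    grid = layer.grid.grid
    nlon = grid.nlon
    band = int(np.floor((band_lon + 180.0) / grid.cell_deg)) % nlon
    west_cols = [(band - off) % nlon for off in range(1, n_neighbors + 1)]
    edge = (band + nlon // 2) % nlon  # 179-180E column
    east_cols = [(edge - j) % nlon for j in range(n_neighbors)]
    neighbor_cols = east_cols + west_cols
    values = layer.grid.values.copy()
    neigh = values[:, neighbor_cols]  # (nlat, 2*n_neighbors)
    counts = (~np.isnan(neigh)).sum(axis=1)
    sums = np.nansum(neigh, axis=1)
    imputed_vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    values[:, band] = imputed_vals
    imputed = layer.imputed.copy()
    imputed[:, band] = ~np.isnan(imputed_vals)
    return CombinedPlasticLayer(
        grid=GlobalDensityGrid(values, grid),
        n_models=layer.n_models,
        imputed=imputed,
    )


def normalize_unit_sum(grid: GlobalDensityGrid) -> GlobalDensityGrid:
    """Divide by the cumulative sum so the grid sums to one (missing cells
    stay missing); scale-invariant and idempotent."""
    return grid.normalize()


def build_combined_layer(
    layers: list[PlasticModelLayer], impute: bool = True
) -> GlobalDensityGrid:
    """combine -> impute band -> normalise: the full plastic-layer chain."""
    combined = combine_models(layers)
    if impute:
        combined = impute_band(combined)
    return normalize_unit_sum(combined.grid)
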