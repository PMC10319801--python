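"""Plastic exposure risk: overlap of normalised animal-density and
plastic-density grids.

The exposure map is the cellwise product of a unit-sum animal utilisation
grid and the unit-sum plastic grid; the score is 10^6 times the summed
map. It is a relative co-occurrence statistic (not an ingestion rate),
bounded by 0 and 10^6, the maximum reached only when both distributions
concentrate on the same single cell. Cells without a plastic estimate
contribute zero, and the fraction of animal mass falling on such cells is
reported so users can judge coverage.

Aggregation follows the month -> season -> population -> species ladder:
season and population scores are unweighted means over months; species
scores are population-size-weighted means over populations, halved for
populations tracked only in the breeding season (to avoid biasing toward
breeding ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GlobalDensityGrid, NormalizationError

SCORE_SCALE = 1e6


@dataclass
class ExposureResult:
    """A score plus its (unnormalised-product) map at some scope."""

    scope: str  # month | season | population | species | all-species
    ids: dict
    score: float
    map: GlobalDensityGrid
    months_included: list = field(default_factory=list)
    missing_plastic_fraction: float = 0.0
    weighting: dict = field(default_factory=dict)


def exposure_map(
    petrel: GlobalDensityGrid, plastic: GlobalDensityGrid
) -> tuple[GlobalDensityGrid, float]:
    """Cellwise product of two normalised grids.

    Returns the product map (zero where plastic is missing) and the
    fraction of animal mass that fell on plastic-missing cells.
    """
    if petrel.grid != plastic.grid:
        raise ValueError("grids are not co-registered")
    if not (petrel.normalized and plastic.normalized):
        raise ValueError("exposure_map requires normalised inputs")
    pet = np.where(np.isnan(petrel.values), 0.0, petrel.values)
    missing = np.isnan(plastic.values)
    pla = np.where(missing, 0.0, plastic.values)
    product = pet * pla
    missing_fraction = float(pet[missing].sum())
    return GlobalDensityGrid(product, petrel.grid), missing_fraction


def exposure_score(map_grid: GlobalDensityGrid) -> float:
    """10^6 x the summed exposure map."""
    return SCORE_SCALE * map_grid.total()


def uniform_plastic_reference(plastic: GlobalDensityGrid) -> float:
    """Score any animal distribution would attain were plastic spread
    evenly over every cell with a plastic estimate: 10^6 / n_cells.

    Replacing all non-missing plastic values by their mean and
    renormalising gives each cell plastic value 1/N, so the product with
    any unit-sum animal grid supported on those cells sums to 1/N,
    independent of the animal distribution.
    """
    n = int((~plastic.missing).sum())
    if n == 0:
        raise NormalizationError("plastic layer has no estimated cells")
    return SCORE_SCALE / n


def month_exposure(
    petrel_month: GlobalDensityGrid,
    plastic: GlobalDensityGrid,
    population_id: str = "",
    month: int = 0,
) -> ExposureResult:
    """Normalise one month's UD grid and score it against the plastic layer."""
    norm = petrel_month if petrel_month.normalized else petrel_month.normalize()
    emap, miss = exposure_map(norm, plastic)
    return ExposureResult(
        scope="month",
        ids={"population_id": population_id, "month": month},
        score=exposure_score(emap),
        map=emap,
        months_included=[month],
        missing_plastic_fraction=miss,
    )


def season_score(monthly_scores: dict[int, float], labels: dict[int, str]) -> dict[str, float]:
    """Mean monthly score per season label; a season with no months is
    absent from the result (not zero)."""
    out: dict[str, list[float]] = {}
    for m, s in monthly_scores.items():
        label = labels.get(m)
        if label in ("breeding", "non-breeding"):
            out.setdefault(label, []).append(s)
    return {k: float(np.mean(v)) for k, v in out.items()}


def population_score(monthly_scores: dict[int, float]) -> float:
    """Unweighted mean over all tracked months (not season-balanced)."""
    if not monthly_scores:
        raise ValueError("population has no tracked months")
    return float(np.mean(list(monthly_scores.values())))


def mean_monthly_map(monthly_maps: list[GlobalDensityGrid]) -> GlobalDensityGrid:
    """Unweighted mean of monthly maps (matches the score being the mean
    of monthly scores)."""
    values = np.mean([m.values for m in monthly_maps], axis=0)
    return GlobalDensityGrid(values, monthly_maps[0].grid)


def coverage_weight(labels: dict[int, str]) -> float:
    """0.5 for populations tracked only in the breeding season, else 1."""
    tracked = {v for v in labels.values() if v in ("breeding", "non-breeding")}
    return 0.5 if tracked == {"breeding"} else 1.0


def species_score(
    population_scores: dict[str, float],
    population_sizes: dict[str, float | None],
    coverage: dict[str, float],
) -> float:
    """Population-size-weighted mean of population scores, each population's
    contribution multiplied by its season-coverage factor.

    Populations with unknown size fall back to equal weights (all sizes
    are then ignored, since mixing known and unknown would be arbitrary).
    """
    pops = list(population_scores)
    if not pops:
        raise ValueError("species has no populations")
    sizes = np.array(
        [np.nan if population_sizes.get(p) is None else float(population_sizes[p]) for p in pops]
    )
    if np.any(np.isnan(sizes)):
        sizes = np.ones(len(pops))
    cov = np.array([coverage.get(p, 1.0) for p in pops])
    scores = np.array([population_scores[p] for p in pops])
    return float(np.sum(sizes * cov * scores) / np.sum(sizes))


def weighted_species_ud(
    population_uds: dict[str, GlobalDensityGrid],
    population_sizes: dict[str, float | None],
) -> GlobalDensityGrid:
    """Species-level distribution: population-size-weighted mean of the
    populations' normalised grids, renormalised to unit sum."""
    pops = list(population_uds)
    sizes = np.array(
        [np.nan if population_sizes.get(p) is None else float(population_sizes[p]) for p in pops]
    )
    if np.any(np.isnan(sizes)):
        sizes = np.ones(len(pops))
    acc = np.zeros(population_uds[pops[0]].grid.shape)
    for p, w in zip(pops, sizes):
        g = population_uds[p]
        g = g if g.normalized else g.normalize()
        acc += w * np.where(np.isnan(g.values), 0.0, g.values)
    return GlobalDensityGrid(acc, population_uds[pops[0]].grid).normalize()


def all_species_map(
    species_uds: dict[str, GlobalDensityGrid],
    coverage: dict[str, float],
    plastic: GlobalDensityGrid,
) -> ExposureResult:
    """Sum species grids with weight 1 (tracked in both seasons) or 0.5
    (breeding only), renormalise to unit sum, and score against plastic."""
    if not species_uds:
        raise ValueError("no species grids supplied")
    first = next(iter(species_uds.values()))
    acc = np.zeros(first.grid.shape)
    for sp, g in species_uds.items():
        g = g if g.normalized else g.normalize()
        acc += coverage.get(sp, 1.0) * np.where(np.isnan(g.values), 0.0, g.values)
    combined = GlobalDensityGrid(acc, first.grid).normalize()
    emap, miss = exposure_map(combined, plastic)
    return ExposureResult(
        scope="all-species",
        ids={},
        score=exposure_score(emap),
        map=emap,
        missing_plastic_fraction=miss,
        weighting={"species_weights": dict(coverage)},
    )


def category_share(
    species_scores: dict[str, float], categories: dict[str, str]
) -> dict[str, float]:
    """Proportion of the summed species scores per IUCN threat category."""
    from .tracks import IUCN_CATEGORIES

    totals: dict[str, float] = {}
    for sp, s in species_scores.items():
        cat = categories.get(sp)
        if cat not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {cat!r} for species {sp!r}")
        totals[cat] = totals.get(cat, 0.0) + s
    grand = sum(totals.values())
    return {cat: v / grand for cat, v in totals.items()}


def richness_map(species_uds: dict[str, GlobalDensityGrid]) -> np.ndarray:
    """Per-cell count of species with positive mass (presence within the
    95% utilisation distributions)."""
    if not species_uds:
        return np.zeros(GlobalDensityGrid.zeros().grid.shape, dtype=int)
    first = next(iter(species_uds.values()))
    count = np.zeros(first.grid.shape, dtype=int)
    for g in species_uds.values():
        vals = np.where(np.isnan(g.values), 0.0, g.values)
        count += (vals > 0).astype(int)
    return count


def format_score(score: float) -> str:
    """Reporting style: 1 decimal place for scores >= 1, 4 significant
    figures below 1; full precision is retained internally."""
    if score >= 1.0:
        return f"{score:.1f}"
    return f"{score:.4g}"


def scores_table(results: list[ExposureResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "scope": r.scope,
                **r.ids,
                "months": ",".join(str(m) for m in r.months_included),
                "score": r.score,
                "missing_plastic_fraction": r.missing_plastic_fraction,
            }
        )
    return pd.DataFrame(rows)
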