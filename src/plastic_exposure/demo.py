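"""The packaged demo world: the fixed synthetic study conditions used by
the worked example, the end-to-end tests and the acceptance script.

Two species, three populations, ~50 individuals and ~40,000 raw locations
over one tracking year:

* ``gyre-pop`` (species ``petrel-A``, GPS, 6-h fixes): colony on the
  eastern edge of the subtropical "gyre" plastic hotspot, wintering inside
  it. The GPS schedule carries a small device-glitch outlier rate so the
  speed filter has work to do, and one month is deliberately sparse
  (< 5 pooled locations) to exercise the monthly sample-size rule.
* ``cold-pop`` (species ``petrel-A``, PTT, 12-h fixes): high-latitude
  colony, wintering far south in low-plastic waters.
* ``austral-pop`` (species ``petrel-B``, GLS, 12-h fixes, 200-km error):
  southern-hemisphere breeder tracked only during its September-March
  breeding season — it exercises the equinox windows, the GLS pass-through
  rules and the 0.5 season-coverage weight.

The published breeding schedule for ``cold-pop`` deliberately includes one
month (September) in which the tracked birds have already left for the
wintering grounds, so the published-label override is exercised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import (
    Hotspot,
    PopulationSpec,
    SyntheticWorld,
    WorldParams,
    build_world,
)

GYRE = Hotspot(lon=-40.0, lat=32.0, amplitude=30.0, scale_km=1000.0)
SOUTH_PATCH = Hotspot(lon=-120.0, lat=-30.0, amplitude=6.0, scale_km=1200.0)


def demo_population_specs() -> list[PopulationSpec]:
    return [
        PopulationSpec(
            population_id="gyre-pop",
            species_id="petrel-A",
            colony_lon=-28.0,
            colony_lat=38.0,
            wintering_lon=-45.0,
            wintering_lat=30.0,
            n_individuals=14,
            breeding_months=frozenset({4, 5, 6, 7, 8}),
            max_foraging_range_km=600.0,
            device="GPS",
            sampling_interval_h=6.0,
            location_error_sd_km=0.05,
            population_size=20000,
            breeding_country="Atlantis",
            iucn_category="LC",
            outlier_rate=0.002,
            outlier_km=1000.0,
            sparse_month=12,
        ),
        PopulationSpec(
            population_id="cold-pop",
            species_id="petrel-A",
            colony_lon=-16.0,
            colony_lat=52.0,
            wintering_lon=-25.0,
            wintering_lat=-42.0,
            n_individuals=20,
            breeding_months=frozenset({4, 5, 6, 7, 8}),
            max_foraging_range_km=800.0,
            device="PTT",
            sampling_interval_h=12.0,
            location_error_sd_km=1.5,
            population_size=5000,
            breeding_country="Borealis",
            iucn_category="VU",
        ),
        PopulationSpec(
            population_id="austral-pop",
            species_id="petrel-B",
            colony_lon=155.0,
            colony_lat=-35.0,
            wintering_lon=170.0,
            wintering_lat=-40.0,
            n_individuals=16,
            breeding_months=frozenset({9, 10, 11, 12, 1, 2, 3}),
            tracked_months=frozenset({9, 10, 11, 12, 1, 2, 3}),
            max_foraging_range_km=900.0,
            device="GLS",
            sampling_interval_h=12.0,
            location_error_sd_km=200.0,
            population_size=10000,
            breeding_country="Australis",
            iucn_category="EN",
        ),
    ]


def demo_world_params() -> WorldParams:
    specs = demo_population_specs()
    return WorldParams(
        land_fraction=0.12,
        land_smoothness=4.0,
        base_density=0.05,
        lognormal_sigma=0.8,
        hotspots=(GYRE, SOUTH_PATCH),
        colonies=tuple(s.colony_record() for s in specs),
    )


def demo_world(seed: int) -> SyntheticWorld:
    return build_world(seed, demo_world_params())


def demo_published_schedules() -> dict[str, pd.Series]:
    """Published monthly breeding schedules per population.

    ``cold-pop``'s schedule wrongly extends breeding into September, when
    the tracked birds are already on migration — the reconciliation rule
    must override that month to non-breeding.
    """
    specs = {s.population_id: s for s in demo_population_specs()}
    out = {}
    for pop, spec in specs.items():
        months = np.arange(1, 13)
        breeding = set(spec.breeding_months)
        if pop == "cold-pop":
            breeding = breeding | {9}
        labels = ["breeding" if m in breeding else "non-breeding" for m in months]
        out[pop] = pd.Series(labels, index=months)
    return out
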