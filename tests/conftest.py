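import numpy as np
import pandas as pd
import pytest

from plastic_exposure.grids import GlobalDensityGrid, GlobalGrid
from plastic_exposure.pipeline import RunConfig, run_pipeline

DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo-world pipeline run shared by the end-to-end tests."""
    outdir = tmp_path_factory.mktemp("demo-run")
    cfg = RunConfig(outdir=str(outdir), seed=DEMO_SEED)
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture
def small_grid():
    """A coarse 10-degree global grid (18x36 cells) for fast grid tests."""
    return GlobalGrid(cell_deg=10.0)


def random_density_grid(rng, grid=None, missing_fraction=0.0):
    grid = grid or GlobalGrid(cell_deg=10.0)
    values = rng.lognormal(0.0, 1.0, size=grid.shape)
    if missing_fraction > 0:
        values[rng.random(grid.shape) < missing_fraction] = np.nan
    return GlobalDensityGrid(values, grid)


def make_track(rows, population="pop", species="sp", device="GPS",
               colony_lon=0.0, colony_lat=0.0):
    """Build a standard-schema track table from (time, lon, lat) tuples."""
    times, lons, lats = zip(*rows) if rows else ((), (), ())
    return pd.DataFrame(
        {
            "dataset_id": f"{population}_{device}",
            "individual_id": f"{population}_ind000",
            "species": species,
            "population": population,
            "colony_lat": colony_lat,
            "colony_lon": colony_lon,
            "device": device,
            "date_time": pd.to_datetime(list(times), utc=True),
            "latitude": list(lats),
            "longitude": list(lons),
        }
    )
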