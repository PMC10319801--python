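"""Synthetic worlds and track simulation: determinism, degenerate
parameters, central-place structure, model-layer noise calibration."""

import numpy as np
import pandas as pd
import pytest

from plastic_exposure import demo
from plastic_exposure.geo import great_circle_km
from plastic_exposure.synthetic import (
    GenerationError,
    Hotspot,
    ParameterError,
    PopulationSpec,
    WorldParams,
    build_world,
    derive_model_layers,
    simulate_population_tracks,
)

SMALL = WorldParams(cell_deg=10.0, land_fraction=0.1, land_smoothness=1.0)


def small_spec(**kw):
    defaults = dict(
        population_id="p",
        species_id="s",
        colony_lon=0.0,
        colony_lat=0.0,
        wintering_lon=30.0,
        wintering_lat=-20.0,
        n_individuals=3,
        breeding_months=frozenset({5, 6}),
        tracked_months=frozenset({5, 6, 11, 12}),
        max_foraging_range_km=300.0,
        sampling_interval_h=12.0,
        location_error_sd_km=0.0,
    )
    defaults.update(kw)
    return PopulationSpec(**defaults)


class TestBuildWorld:
    def test_seeded_determinism(self):
        w1 = build_world(42, SMALL)
        w2 = build_world(42, SMALL)
        np.testing.assert_array_equal(w1.land_mask, w2.land_mask)
        np.testing.assert_array_equal(w1.plastic_truth, w2.plastic_truth)
        for m1, m2 in zip(w1.model_masks, w2.model_masks):
            np.testing.assert_array_equal(m1, m2)

    def test_different_seeds_differ(self):
        w1 = build_world(1, SMALL)
        w2 = build_world(2, SMALL)
        assert not np.array_equal(w1.plastic_truth, w2.plastic_truth)

    def test_zero_hotspot_amplitude_homogeneous(self):
        params = WorldParams(
            cell_deg=10.0,
            land_fraction=0.0,
            lognormal_sigma=0.0,
            hotspots=(Hotspot(0.0, 0.0, 0.0, 1000.0),),
        )
        w = build_world(0, params)
        np.testing.assert_allclose(w.plastic_truth, params.base_density)

    def test_zero_land_fraction_all_ocean(self):
        params = WorldParams(cell_deg=10.0, land_fraction=0.0)
        w = build_world(0, params)
        assert not w.land_mask.any()
        assert np.all(np.isfinite(w.plastic_truth))

    def test_plastic_positive_on_ocean(self):
        w = build_world(3, SMALL)
        ocean = ~w.land_mask
        assert np.all(w.plastic_truth[ocean] > 0)
        assert np.all(np.isnan(w.plastic_truth[w.land_mask]))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(hotspots=()),
            dict(base_density=0.0),
            dict(land_fraction=1.5),
            dict(hotspots=(Hotspot(0, 0, -1.0, 100.0),)),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            build_world(0, WorldParams(**bad))

    def test_fallback_mask_cells_exist(self):
        w = build_world(5, SMALL)
        missing = np.stack(w.model_masks).sum(axis=0)
        ocean = ~w.land_mask
        assert np.any((missing == 1) & ocean)
        assert np.any((missing == 2) & ocean)


class TestSimulateTracks:
    world = build_world(7, SMALL)

    def test_determinism(self):
        t1 = simulate_population_tracks(self.world, small_spec(), 11)
        t2 = simulate_population_tracks(self.world, small_spec(), 11)
        pd.testing.assert_frame_equal(t1, t2)

    def test_breeding_points_within_foraging_range(self):
        spec = small_spec(max_foraging_range_km=300.0, location_error_sd_km=0.0)
        tracks = simulate_population_tracks(self.world, spec, 1)
        breeding = tracks[pd.to_datetime(tracks["date_time"]).dt.month.isin([5, 6])]
        d = great_circle_km(
            breeding["longitude"].to_numpy(),
            breeding["latitude"].to_numpy(),
            spec.colony_lon,
            spec.colony_lat,
        )
        assert np.all(d <= 300.0 + 1e-6)

    def test_distant_wintering_ground(self):
        # wintering centroid ~8000 km away: non-breeding months are much
        # further from the colony than breeding months
        spec = small_spec(wintering_lon=75.0, wintering_lat=5.0)
        tracks = simulate_population_tracks(self.world, spec, 2)
        months = pd.to_datetime(tracks["date_time"]).dt.month
        d = great_circle_km(
            tracks["longitude"].to_numpy(),
            tracks["latitude"].to_numpy(),
            spec.colony_lon,
            spec.colony_lat,
        )
        breeding_mean = d[months.isin([5, 6]).to_numpy()].mean()
        winter_mean = d[months.isin([11, 12]).to_numpy()].mean()
        assert winter_mean > breeding_mean
        assert winter_mean > 5000.0

    def test_zero_individuals_empty(self):
        tracks = simulate_population_tracks(self.world, small_spec(n_individuals=0), 1)
        assert len(tracks) == 0

    def test_landlocked_colony_raises(self):
        world = build_world(7, SMALL)
        world.land_mask[:] = True
        with pytest.raises(GenerationError):
            simulate_population_tracks(world, small_spec(), 1)


class TestModelLayers:
    world = build_world(13, SMALL)

    def test_zero_noise_recovers_truth(self):
        layers = derive_model_layers(self.world, 0, noise_sigma=0.0)
        jointly = ~np.any(np.stack(self.world.model_masks), axis=0)
        for layer in layers:
            np.testing.assert_allclose(
                layer.grid.values[jointly], self.world.plastic_truth[jointly]
            )

    def test_all_masked_cell_missing_everywhere(self):
        layers = derive_model_layers(self.world, 1)
        all_missing = np.all(np.stack(self.world.model_masks), axis=0)
        assert all_missing.any()  # polar caps overlap
        for layer in layers:
            assert np.all(np.isnan(layer.grid.values[all_missing]))

    def test_noise_median_one_gm_converges_to_truth(self):
        # across seeds, the per-cell mean log deviation from truth is zero:
        # the geometric mean over >= 200 replicate layers approaches truth
        sigma = 0.7
        n_seeds = 200
        jointly = ~np.any(np.stack(self.world.model_masks), axis=0)
        cells = np.argwhere(jointly)[:5]
        logs = np.zeros((n_seeds, len(cells)))
        for s in range(n_seeds):
            layer = derive_model_layers(self.world, 1000 + s, noise_sigma=sigma)[0]
            logs[s] = [np.log(layer.grid.values[i, j]) for i, j in cells]
        truth = np.array([np.log(self.world.plastic_truth[i, j]) for i, j in cells])
        se = sigma / np.sqrt(n_seeds)
        assert np.all(np.abs(logs.mean(axis=0) - truth) < 3 * se)


@pytest.fixture(scope="module")
def demo_tracks():
    world = demo.demo_world(1)
    frames = [
        simulate_population_tracks(world, spec, 1)
        for spec in demo.demo_population_specs()
    ]
    return pd.concat(frames, ignore_index=True)


class TestDemoWorldCoverage:
    """The packaged demo world must exercise every preprocessing rule."""

    def test_speed_outlier_present(self, demo_tracks):
        gps = demo_tracks[demo_tracks["device"] == "GPS"]
        speeds = []
        for _, sub in gps.groupby("individual_id"):
            lon = sub["longitude"].to_numpy()
            lat = sub["latitude"].to_numpy()
            th = pd.to_datetime(sub["date_time"]).astype("int64").to_numpy() / 3.6e12
            speeds.append(
                great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) / np.diff(th)
            )
        assert np.concatenate(speeds).max() > 90.0

    def test_equinox_window_gls_points_present(self, demo_tracks):
        gls = demo_tracks[demo_tracks["device"] == "GLS"]
        days = pd.to_datetime(gls["date_time"]).dt.strftime("%m-%d")
        assert (days == "03-10").any()  # inside the March window
        assert (days == "09-20").any()  # inside the September window

    def test_points_within_colony_buffer_present(self, demo_tracks):
        gps = demo_tracks[demo_tracks["device"] == "GPS"]
        d = great_circle_km(
            gps["longitude"].to_numpy(),
            gps["latitude"].to_numpy(),
            gps["colony_lon"].to_numpy(),
            gps["colony_lat"].to_numpy(),
        )
        assert (d < 5.0).any()

    def test_sparse_month_below_five_locations(self, demo_tracks):
        gyre = demo_tracks[demo_tracks["population"] == "gyre-pop"]
        months = pd.to_datetime(gyre["date_time"]).dt.month
        assert 0 < (months == 12).sum() < 5
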