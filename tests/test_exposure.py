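"""Exposure scores: the product statistic, its reference value, the
aggregation ladder and its invariances."""

import numpy as np
import pytest

from plastic_exposure.exposure import (
    all_species_map,
    category_share,
    coverage_weight,
    exposure_map,
    exposure_score,
    population_score,
    richness_map,
    season_score,
    species_score,
    uniform_plastic_reference,
)
from plastic_exposure.grids import GlobalDensityGrid, GlobalGrid

GRID = GlobalGrid(cell_deg=90.0)  # 2x4 global grid for hand computation


def grid_of(values, normalized=False):
    return GlobalDensityGrid(np.asarray(values, dtype=float), GRID, normalized)


PETREL = grid_of([[0.2, 0.8, 0, 0], [0, 0, 0, 0]], normalized=True)


class TestExposureMap:
    def test_hand_computed_product(self):
        plastic = grid_of([[0.75, 0.25, 0, 0], [0, 0, 0, 0]], normalized=True)
        emap, miss = exposure_map(PETREL, plastic)
        np.testing.assert_allclose(emap.values[0, :2], [0.15, 0.2])
        assert exposure_score(emap) == pytest.approx(350000.0)
        assert miss == 0.0

    def test_disjoint_supports_zero(self):
        plastic = grid_of([[0, 0, 0.5, 0.5], [0, 0, 0, 0]], normalized=True)
        emap, _ = exposure_map(PETREL, plastic)
        assert exposure_score(emap) == 0.0

    def test_missing_plastic_flagged(self):
        plastic = grid_of([[np.nan, 1.0, 0, 0], [0, 0, 0, 0]], normalized=True)
        emap, miss = exposure_map(PETREL, plastic)
        assert emap.values[0, 0] == 0.0
        assert miss == pytest.approx(0.2)

    def test_requires_normalised_inputs(self):
        with pytest.raises(ValueError):
            exposure_map(grid_of([[1, 1, 1, 1], [1, 1, 1, 1]]), PETREL)

    def test_identical_single_cell_hits_maximum(self):
        one = grid_of([[1.0, 0, 0, 0], [0, 0, 0, 0]], normalized=True)
        emap, _ = exposure_map(one, one)
        assert exposure_score(emap) == pytest.approx(1e6)

    def test_scale_invariance_of_raw_inputs(self):
        rng = np.random.default_rng(2)
        pet_raw = rng.random(GRID.shape)
        pla_raw = rng.lognormal(0, 1, GRID.shape)
        s1 = exposure_score(
            exposure_map(
                GlobalDensityGrid(pet_raw, GRID).normalize(),
                GlobalDensityGrid(pla_raw, GRID).normalize(),
            )[0]
        )
        s2 = exposure_score(
            exposure_map(
                GlobalDensityGrid(pet_raw * 7.3, GRID).normalize(),
                GlobalDensityGrid(pla_raw * 1234.5, GRID).normalize(),
            )[0]
        )
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_concentration_maximises_score(self):
        # among all petrel distributions, a point mass on the argmax
        # plastic cell gives the largest score (brute force over cells)
        rng = np.random.default_rng(3)
        plastic = GlobalDensityGrid(rng.random(GRID.shape), GRID).normalize()
        best = 0.0
        for i in range(GRID.nlat):
            for j in range(GRID.nlon):
                pet = np.zeros(GRID.shape)
                pet[i, j] = 1.0
                s = exposure_score(
                    exposure_map(GlobalDensityGrid(pet, GRID, True), plastic)[0]
                )
                best = max(best, s)
        assert best == pytest.approx(1e6 * np.max(plastic.values))
        rand_pet = GlobalDensityGrid(rng.random(GRID.shape), GRID).normalize()
        s_rand = exposure_score(exposure_map(rand_pet, plastic)[0])
        assert s_rand <= best


class TestUniformReference:
    def test_equals_1e6_over_n(self):
        values = np.full(GRID.shape, np.nan)
        values[0, :3] = [1.0, 5.0, 9.0]
        assert uniform_plastic_reference(grid_of(values)) == pytest.approx(1e6 / 3)

    def test_independent_of_petrel_distribution(self):
        # the reference depends only on the plastic cell count, so any two
        # animal distributions supported on estimated cells share it
        values = np.ones(GRID.shape)
        ref = uniform_plastic_reference(grid_of(values))
        uniform_plastic = grid_of(values).normalize()
        for seed in (0, 1):
            pet = GlobalDensityGrid(
                np.random.default_rng(seed).random(GRID.shape), GRID
            ).normalize()
            s = exposure_score(exposure_map(pet, uniform_plastic)[0])
            assert s == pytest.approx(ref, rel=1e-12)


class TestAggregationLadder:
    def test_season_means(self):
        scores = {1: 10.0, 2: 20.0, 3: 30.0, 7: 5.0}
        labels = {1: "breeding", 2: "breeding", 3: "breeding", 7: "non-breeding"}
        out = season_score(scores, labels)
        assert out == {"breeding": 20.0, "non-breeding": 5.0}

    def test_absent_season_absent_not_zero(self):
        out = season_score({1: 10.0}, {1: "breeding"})
        assert "non-breeding" not in out

    def test_population_mean_over_all_months(self):
        assert population_score({1: 0.0, 2: 100.0}) == 50.0
        assert population_score({5: 42.0}) == 42.0

    def test_coverage_weight(self):
        assert coverage_weight({1: "breeding", 2: "breeding"}) == 0.5
        assert coverage_weight({1: "breeding", 2: "non-breeding"}) == 1.0

    def test_species_weighted_mean(self):
        s = species_score(
            {"a": 10.0, "b": 20.0},
            {"a": 1000, "b": 3000},
            {"a": 1.0, "b": 1.0},
        )
        assert s == pytest.approx(17.5)

    def test_breeding_only_population_halved(self):
        s = species_score({"a": 40.0}, {"a": 5000}, {"a": 0.5})
        assert s == pytest.approx(20.0)

    def test_missing_sizes_fall_back_to_equal_weights(self):
        s = species_score(
            {"a": 10.0, "b": 30.0}, {"a": None, "b": 3000}, {"a": 1.0, "b": 1.0}
        )
        assert s == pytest.approx(20.0)


class TestAllSpecies:
    def test_single_species_identity(self):
        sp = grid_of([[0.5, 0.5, 0, 0], [0, 0, 0, 0]], normalized=True)
        plastic = grid_of(np.full(GRID.shape, 1.0)).normalize()
        res = all_species_map({"a": sp}, {"a": 1.0}, plastic)
        emap, _ = exposure_map(sp, plastic)
        np.testing.assert_allclose(res.map.values, emap.values)

    def test_identical_grids_weights_absorbed(self):
        sp = grid_of([[0.5, 0.5, 0, 0], [0, 0, 0, 0]], normalized=True)
        plastic = grid_of(np.full(GRID.shape, 1.0)).normalize()
        r1 = all_species_map({"a": sp, "b": sp}, {"a": 1.0, "b": 0.5}, plastic)
        r2 = all_species_map({"a": sp}, {"a": 1.0}, plastic)
        np.testing.assert_allclose(r1.map.values, r2.map.values)

    def test_disjoint_single_cells_split_two_thirds(self):
        a = grid_of([[1.0, 0, 0, 0], [0, 0, 0, 0]], normalized=True)
        b = grid_of([[0, 1.0, 0, 0], [0, 0, 0, 0]], normalized=True)
        plastic = grid_of(np.full(GRID.shape, 1.0)).normalize()
        res = all_species_map({"a": a, "b": b}, {"a": 1.0, "b": 0.5}, plastic)
        combined = res.map.values * GRID.ncells  # divide out uniform plastic
        assert combined[0, 0] == pytest.approx(2.0 / 3.0)
        assert combined[0, 1] == pytest.approx(1.0 / 3.0)


class TestCategoryAndRichness:
    def test_equal_split(self):
        shares = category_share({"a": 100.0, "b": 100.0}, {"a": "CR", "b": "LC"})
        assert shares == {"CR": 0.5, "LC": 0.5}

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        scores = {f"s{i}": float(rng.random()) for i in range(10)}
        cats = {f"s{i}": ["LC", "NT", "VU", "EN", "CR"][i % 5] for i in range(10)}
        assert sum(category_share(scores, cats).values()) == pytest.approx(1.0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            category_share({"a": 1.0}, {"a": "XX"})

    def test_richness_counts_overlap(self):
        a = grid_of([[1.0, 1.0, 0, 0], [0, 0, 0, 0]], normalized=True)
        b = grid_of([[0, 1.0, 1.0, 0], [0, 0, 0, 0]], normalized=True)
        r = richness_map({"a": a, "b": b})
        assert r[0, 1] == 2
        assert r[0, 0] == 1 and r[0, 2] == 1
        assert r.max() <= 2
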