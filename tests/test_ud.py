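"""Kernel utilisation distributions: closed forms, oracle equivalence,
isopleth geometry, land trimming and mass-conserving aggregation."""

import numpy as np
import pandas as pd
import pytest

from plastic_exposure.geo import AzimuthalEqualArea, great_circle_km
from plastic_exposure.grids import GlobalGrid
from plastic_exposure.landmask import from_grid_mask, ocean_everywhere
from plastic_exposure.ud import (
    FineUD,
    aggregate_to_global,
    apply_isopleth,
    kernel_ud,
    month_filter,
    trim_land,
)

from conftest import make_track


def points_df(lonlat):
    rows = [
        (pd.Timestamp("2014-06-01", tz="UTC") + pd.Timedelta(hours=12 * i), lon, lat)
        for i, (lon, lat) in enumerate(lonlat)
    ]
    return make_track(rows)


class TestMonthFilter:
    def _df(self, n_may, n_june):
        rows = [
            (pd.Timestamp("2014-05-01", tz="UTC") + pd.Timedelta(hours=i), 1.0, 1.0)
            for i in range(n_may)
        ] + [
            (pd.Timestamp("2014-06-01", tz="UTC") + pd.Timedelta(hours=i), 1.0, 1.0)
            for i in range(n_june)
        ]
        return make_track(rows)

    def test_threshold_is_five(self):
        out = month_filter(self._df(4, 5))
        assert set(out) == {6}

    def test_empty_input(self):
        assert month_filter(self._df(0, 0).iloc[0:0]) == {}

    def test_all_months_retained(self):
        out = month_filter(self._df(6, 7))
        assert set(out) == {5, 6}
        assert len(out[5]) == 6


class TestKernelUD:
    def test_single_point_peak_density(self):
        h = 200.0
        ud = kernel_ud(points_df([(0.0, 0.0)]), h=h, cell_km=10.0)
        peak_mass = ud.mass.max()
        expected_density = 1.0 / (2.0 * np.pi * h * h)
        # cell centres are offset from the point by <= half a cell; compare
        # the peak cell's density against the kernel evaluated there
        assert peak_mass / 100.0 == pytest.approx(expected_density, rel=1e-3)

    def test_two_distant_modes_hold_half_mass_each(self):
        # 5000 km apart: kernels effectively disjoint
        proj = AzimuthalEqualArea(0.0, 0.0)
        df = points_df([(0.0, 0.0), (45.0, 0.0)])  # ~5000 km on the equator
        ud = kernel_ud(df, projection=proj, h=200.0, cell_km=25.0, margin_bandwidths=6.5)
        x2d, _ = ud.cell_centers_xy()
        left = ud.mass[x2d < 2500.0].sum()
        right = ud.mass[x2d >= 2500.0].sum()
        assert left == pytest.approx(0.5, abs=1e-6)
        assert right == pytest.approx(0.5, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1.0, 1.0, size=(12, 2))
        df = points_df([(lon, lat) for lon, lat in pts])
        proj = AzimuthalEqualArea(0.0, 0.0)
        h, cell = 150.0, 40.0
        ud = kernel_ud(df, projection=proj, h=h, cell_km=cell)
        px, py = proj.forward(df["longitude"].to_numpy(), df["latitude"].to_numpy())
        x2d, y2d = ud.cell_centers_xy()
        oracle = np.zeros_like(ud.mass)
        for xi, yi in zip(px, py):  # direct double loop over points x cells
            oracle += np.exp(
                -0.5 * (((x2d - xi) / h) ** 2 + ((y2d - yi) / h) ** 2)
            )
        oracle *= cell * cell / (len(px) * 2.0 * np.pi * h * h)
        np.testing.assert_allclose(ud.mass, oracle, atol=1e-12)

    def test_duplicating_sample_leaves_ud_unchanged(self):
        df1 = points_df([(0.0, 0.0), (0.5, 0.2), (0.1, -0.4)])
        df2 = points_df([(0.0, 0.0), (0.5, 0.2), (0.1, -0.4)] * 2)
        proj = AzimuthalEqualArea(0.0, 0.0)
        u1 = kernel_ud(df1, projection=proj)
        u2 = kernel_ud(df2, projection=proj)
        np.testing.assert_allclose(u1.mass, u2.mass, atol=1e-15)

    def test_total_mass_near_one(self):
        ud = kernel_ud(points_df([(0.0, 0.0), (1.0, 1.0)]))
        assert 0.99 < ud.total_mass <= 1.0


class TestIsopleth:
    def test_uniform_cells(self):
        mass = np.full((10, 10), 0.01)
        ud = FineUD("p", 1, AzimuthalEqualArea(0, 0), 10.0, 0.0, 0.0, mass)
        out = apply_isopleth(ud, 0.95)
        assert out.isopleth_mask.sum() == 95

    def test_single_cell(self):
        mass = np.zeros((5, 5))
        mass[2, 2] = 1.0
        ud = FineUD("p", 1, AzimuthalEqualArea(0, 0), 10.0, 0.0, 0.0, mass)
        out = apply_isopleth(ud, 0.95)
        assert out.isopleth_mask.sum() == 1
        assert out.mass[2, 2] == 1.0

    def test_gaussian_radius_closed_form(self):
        # 95% of an isotropic Gaussian lies within h*sqrt(2 ln 20)
        h, cell = 200.0, 10.0
        ud = kernel_ud(points_df([(0.0, 0.0)]), h=h, cell_km=cell, margin_bandwidths=4.0)
        out = apply_isopleth(ud, 0.95)
        x2d, y2d = out.cell_centers_xy()
        proj = out.projection
        px, py = proj.forward(0.0, 0.0)
        r = np.hypot(x2d - px, y2d - py)[out.isopleth_mask]
        expected = h * np.sqrt(2.0 * np.log(20.0))
        assert r.max() == pytest.approx(expected, abs=cell)
        retained = out.mass.sum() / ud.mass.sum()
        assert 0.95 <= retained < 0.96

    def test_mass_outside_mask_zero_and_not_renormalised(self):
        rng = np.random.default_rng(0)
        mass = rng.random((20, 20))
        ud = FineUD("p", 1, AzimuthalEqualArea(0, 0), 10.0, 0.0, 0.0, mass)
        out = apply_isopleth(ud, 0.95)
        assert np.all(out.mass[~out.isopleth_mask] == 0.0)
        np.testing.assert_array_equal(out.mass[out.isopleth_mask], mass[out.isopleth_mask])


class TestLandTrim:
    def _ud(self):
        return kernel_ud(points_df([(0.0, 0.0), (2.0, 0.0)]), cell_km=50.0)

    def test_all_ocean_identity(self):
        ud = self._ud()
        out = trim_land(ud, ocean_everywhere)
        np.testing.assert_array_equal(out.mass, ud.mass)

    def test_all_land_zeroes(self):
        ud = self._ud()
        out = trim_land(ud, lambda lon, lat: np.ones(np.shape(lon), dtype=bool))
        assert out.total_mass == 0.0

    def test_half_land_preserves_ocean_mass(self):
        ud = self._ud()
        is_land = lambda lon, lat: np.asarray(lon) > 1.0  # noqa: E731
        out = trim_land(ud, is_land)
        lon, _ = ud.cell_centers_lonlat()
        expected = ud.mass[np.asarray(lon) <= 1.0].sum()
        assert out.total_mass == pytest.approx(expected, rel=1e-12)


class TestAggregate:
    def test_mass_conserved(self):
        ud = kernel_ud(points_df([(10.0, 20.0), (12.0, 22.0)]))
        out = aggregate_to_global(ud)
        assert out.total() == pytest.approx(ud.total_mass, abs=1e-9)

    def test_all_in_one_cell(self):
        proj = AzimuthalEqualArea(10.5, 20.5)
        mass = np.full((4, 4), 0.0625)
        # 4x4 fine cells of 10 km centred on (10.5, 20.5): within one degree
        ud = FineUD("p", 1, proj, 10.0, -20.0, -20.0, mass)
        out = aggregate_to_global(ud)
        ilat, ilon = out.grid.cell_index(10.5, 20.5)
        assert out.values[ilat, ilon] == pytest.approx(1.0)
        assert (out.values > 0).sum() == 1

    def test_split_matches_centre_assignment_oracle(self):
        ud = kernel_ud(points_df([(0.3, 0.0), (-0.4, 0.1)]), cell_km=30.0)
        out = aggregate_to_global(ud)
        lon, lat = ud.cell_centers_lonlat()
        grid = GlobalGrid()
        oracle = np.zeros(grid.shape)
        for lo, la, m in zip(
            np.asarray(lon).ravel(), np.asarray(lat).ravel(), ud.mass.ravel()
        ):
            i, j = grid.cell_index(lo, la)
            oracle[i, j] += m
        np.testing.assert_allclose(out.values, oracle, atol=1e-15)


class TestMixtureRecovery:
    def test_aggregated_ud_recovers_mixture_weights(self):
        # two clusters ~3000 km apart with weights 0.7 / 0.3
        rng = np.random.default_rng(11)
        n, w = 2000, 0.7
        n1 = rng.binomial(n, w)
        sd_deg = 1.5
        pts1 = np.column_stack(
            [rng.normal(0.0, sd_deg, n1), rng.normal(0.0, sd_deg, n1)]
        )
        pts2 = np.column_stack(
            [rng.normal(28.0, sd_deg, n - n1), rng.normal(0.0, sd_deg, n - n1)]
        )
        df = points_df([(lo, la) for lo, la in np.vstack([pts1, pts2])])
        ud = kernel_ud(df, cell_km=25.0)
        agg = aggregate_to_global(ud)
        _, lon2d = agg.grid.cell_centers()
        west = agg.values[lon2d < 14.0].sum() / agg.total()
        se = np.sqrt(w * (1 - w) / n)
        assert abs(west - w) < 3 * se + 1e-3
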