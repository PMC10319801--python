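"""Seeded synthetic worlds and tracking datasets.

Real petrel tracking data are restricted-access, so every downstream stage
is exercised against synthetic data with the same statistical structure:

* a global 1x1-degree world with patchy land, a strictly positive
  lognormal plastic field with Gaussian "gyre" hotspots, three per-model
  missing-data masks, and toy rectangular jurisdictions;
* central-place foraging tracks during breeding months (out-and-back
  biased random walks capped at a maximum foraging range from the colony)
  and wintering-ground tracks clustered round a distant centroid during
  non-breeding months, with per-device sampling schedules and isotropic
  Gaussian location error.

Everything is a pure function of (seed, parameters): the same inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .geo import EARTH_RADIUS_KM, AzimuthalEqualArea, normalize_lon, validate_lonlat
from .grids import GlobalDensityGrid, GlobalGrid
from .jurisdiction import JurisdictionLayer, JurisdictionPolygon
from .plastic import PlasticModelLayer
from .tracks import TRACK_COLUMNS, ColonyRecord

MODEL_NAMES = ("maximenko-like", "lebreton-like", "vansebille-like")


class ParameterError(ValueError):
    """Invalid synthetic-world parameters."""


class GenerationError(RuntimeError):
    """World/population mismatch (e.g. land-locked colony)."""


@dataclass(frozen=True)
class Hotspot:
    """A Gaussian bump multiplying the background plastic field."""

    lon: float
    lat: float
    amplitude: float  # multiplicative peak excess over background (>= 0)
    scale_km: float  # e-folding ~ Gaussian sd of the bump


@dataclass(frozen=True)
class WorldParams:
    cell_deg: float = 1.0
    land_fraction: float = 0.12
    land_smoothness: float = 4.0  # cells; larger -> fewer, bigger continents
    base_density: float = 0.05  # pieces km^-2, background median
    lognormal_sigma: float = 0.8  # log-scale spatial patchiness
    hotspots: tuple[Hotspot, ...] = (Hotspot(-40.0, 32.0, 30.0, 1000.0),)
    polar_caps: tuple[float, float, float] = (60.0, 65.0, 70.0)  # per-model |lat| cut
    coastal_missing_fraction: float = 0.15  # per-model random coastal gaps
    colonies: tuple[ColonyRecord, ...] = ()
    jurisdictions: JurisdictionLayer | None = None

    def validate(self) -> None:
        if self.base_density <= 0 or self.lognormal_sigma < 0:
            raise ParameterError("field scales must be positive")
        if len(self.hotspots) < 1:
            raise ParameterError("at least one hotspot required")
        if any(h.amplitude < 0 or h.scale_km <= 0 for h in self.hotspots):
            raise ParameterError("hotspot amplitude >= 0 and scale > 0 required")
        if not 0.0 <= self.land_fraction < 1.0:
            raise ParameterError("land_fraction must be in [0, 1)")


@dataclass
class SyntheticWorld:
    seed: int
    grid: GlobalGrid
    land_mask: np.ndarray  # bool, True = land
    plastic_truth: np.ndarray  # pieces km^-2; NaN on land, > 0 on ocean
    model_masks: list[np.ndarray]  # bool, True = missing in that model
    jurisdictions: JurisdictionLayer
    colonies: dict[str, ColonyRecord]
    params: WorldParams = field(default_factory=WorldParams)


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to simulate one tracked breeding population."""

    population_id: str
    species_id: str
    colony_lon: float
    colony_lat: float
    wintering_lon: float
    wintering_lat: float
    n_individuals: int
    breeding_months: frozenset = frozenset({4, 5, 6, 7, 8})
    tracked_months: frozenset | None = None  # None -> all 12
    max_foraging_range_km: float = 500.0
    device: str = "GPS"
    sampling_interval_h: float = 12.0
    location_error_sd_km: float = 0.05
    population_size: int | None = None  # breeding pairs
    breeding_country: str = ""
    iucn_category: str = "LC"
    flight_speed_kmh: float = 35.0
    winter_spread_km: float = 450.0
    outlier_rate: float = 0.0  # device-glitch probability per fix
    outlier_km: float = 400.0
    sparse_month: int | None = None  # keep only a few fixes in this month
    sparse_keep: int = 3
    year: int = 2014

    def validate(self) -> None:
        validate_lonlat(self.colony_lon, self.colony_lat)
        validate_lonlat(self.wintering_lon, self.wintering_lat)
        if self.n_individuals < 0:
            raise ParameterError("n_individuals must be >= 0")
        if self.max_foraging_range_km < 0 or self.location_error_sd_km < 0:
            raise ParameterError("ranges and errors must be non-negative")
        if not self.breeding_months <= set(range(1, 13)):
            raise ParameterError("breeding months must be in 1..12")
        if self.device not in ("GPS", "PTT", "GLS"):
            raise ParameterError(f"unknown device {self.device!r}")

    def colony_record(self) -> ColonyRecord:
        return ColonyRecord(
            population_id=self.population_id,
            species_id=self.species_id,
            colony_lon=self.colony_lon,
            colony_lat=self.colony_lat,
            breeding_country=self.breeding_country,
            population_size=self.population_size,
            iucn_category=self.iucn_category,
        )


# --- world ----------------------------------------------------------------


def _land_mask(rng: np.random.Generator, params: WorldParams, grid: GlobalGrid):
    if params.land_fraction == 0.0:
        return np.zeros(grid.shape, dtype=bool)
    noise = rng.standard_normal(grid.shape)
    smooth = gaussian_filter(noise, sigma=params.land_smoothness, mode="wrap")
    threshold = np.quantile(smooth, 1.0 - params.land_fraction)
    mask = smooth > threshold
    # colonies sit on coastal points: keep each colony's own cell ocean so
    # its population has at-sea habitat in the immediate neighbourhood
    for colony in params.colonies:
        ilat, ilon = grid.cell_index(colony.colony_lon, colony.colony_lat)
        mask[ilat, ilon] = False
    return mask


def _plastic_truth(rng, params: WorldParams, grid: GlobalGrid, land: np.ndarray):
    lat2d, lon2d = grid.cell_centers()
    factor = np.ones(grid.shape)
    for h in params.hotspots:
        # chordal distance on the unit sphere, scaled to km: smooth,
        # antimeridian-safe measure of proximity to the hotspot centre
        lam, phi = np.radians(lon2d), np.radians(lat2d)
        lam0, phi0 = np.radians(h.lon), np.radians(h.lat)
        cosang = np.clip(
            np.sin(phi) * np.sin(phi0) + np.cos(phi) * np.cos(phi0) * np.cos(lam - lam0),
            -1.0,
            1.0,
        )
        d_km = EARTH_RADIUS_KM * np.arccos(cosang)
        factor += h.amplitude * np.exp(-0.5 * (d_km / h.scale_km) ** 2)
    noise = np.exp(params.lognormal_sigma * rng.standard_normal(grid.shape))
    truth = params.base_density * factor * noise
    truth[land] = np.nan
    return truth


def _model_masks(rng, params: WorldParams, grid: GlobalGrid, land: np.ndarray):
    lat2d, _ = grid.cell_centers()
    coastal = np.zeros(grid.shape, dtype=bool)
    if land.any():
        padded = np.zeros_like(land)
        for dlat in (-1, 0, 1):
            for dlon in (-1, 0, 1):
                padded |= np.roll(np.roll(land, dlat, axis=0), dlon, axis=1)
        coastal = padded & ~land
    masks = []
    for cap in params.polar_caps:
        mask = np.abs(lat2d) > cap
        mask |= coastal & (rng.random(grid.shape) < params.coastal_missing_fraction)
        mask |= land
        masks.append(mask)
    # guarantee both fallback branches of the geometric-mean rule: one
    # ocean cell missing in exactly one model, one missing in exactly two
    ocean_low = np.argwhere(~land & (np.abs(lat2d) < 45.0))
    if len(ocean_low) >= 2:
        pick = ocean_low[rng.choice(len(ocean_low), size=2, replace=False)]
        (r1, c1), (r2, c2) = pick
        masks[0][r1, c1] = True
        masks[1][r1, c1] = masks[2][r1, c1] = False
        masks[0][r2, c2] = masks[1][r2, c2] = True
        masks[2][r2, c2] = False
    return masks


def _default_jurisdictions(colonies) -> JurisdictionLayer:
    """Toy rectangles: one 12x12-degree EEZ per (first three) colonies'
    sovereigns, plus one joint regime between the first two."""
    polys = []
    seen = set()
    for colony in colonies[:3]:
        country = colony.breeding_country or f"Sovereign-{colony.population_id}"
        if country in seen:
            continue
        seen.add(country)
        lon, lat = colony.colony_lon, colony.colony_lat
        geom = box(lon - 6, max(lat - 6, -89), lon + 6, min(lat + 6, 89))
        category = "theoretical-EEZ" if len(polys) == 2 else "EEZ"
        polys.append(JurisdictionPolygon(f"{country} EEZ", [country], category, geom))
    if len(polys) >= 2:
        a, b = polys[0], polys[1]
        cx = (a.geometry.centroid.x + b.geometry.centroid.x) / 2
        cy = (a.geometry.centroid.y + b.geometry.centroid.y) / 2
        polys.append(
            JurisdictionPolygon(
                "Joint regime",
                [a.sovereigns[0], b.sovereigns[0]],
                "joint-regime",
                box(cx - 4, max(cy - 4, -89), cx + 4, min(cy + 4, 89)),
            )
        )
    return JurisdictionLayer(polys)


def build_world(seed: int, params: WorldParams | None = None) -> SyntheticWorld:
    """Deterministically generate a synthetic world from (seed, params)."""
    params = params or WorldParams()
    params.validate()
    grid = GlobalGrid(params.cell_deg)
    rng = np.random.default_rng(seed)
    land = _land_mask(rng, params, grid)
    truth = _plastic_truth(rng, params, grid, land)
    masks = _model_masks(rng, params, grid, land)
    jurisdictions = params.jurisdictions or _default_jurisdictions(list(params.colonies))
    colonies = {c.population_id: c for c in params.colonies}
    return SyntheticWorld(seed, grid, land, truth, masks, jurisdictions, colonies, params)


def derive_model_layers(
    world: SyntheticWorld, seed: int, noise_sigma: float = 0.7
) -> list[PlasticModelLayer]:
    """Three model outputs: plastic truth times independent median-one
    lognormal noise, each with its model's missing mask applied."""
    rng = np.random.default_rng(seed)
    layers = []
    for name, mask in zip(MODEL_NAMES, world.model_masks):
        noise = np.exp(noise_sigma * rng.standard_normal(world.grid.shape))
        values = world.plastic_truth * noise
        values[mask] = np.nan
        layers.append(PlasticModelLayer(name, GlobalDensityGrid(values, world.grid)))
    return layers


# --- tracks ---------------------------------------------------------------


def _colony_has_ocean(world: SyntheticWorld, lon: float, lat: float) -> bool:
    ilat, ilon = world.grid.cell_index(lon, lat)
    nlat, nlon = world.grid.shape
    for dlat in (-1, 0, 1):
        for dlon in (-1, 0, 1):
            r = min(max(int(ilat) + dlat, 0), nlat - 1)
            c = (int(ilon) + dlon) % nlon
            if not world.land_mask[r, c]:
                return True
    return False


def _plane_cap_radius(max_range_km: float) -> float:
    """Planar LAEA radius such that the great-circle distance from the
    projection centre never exceeds max_range_km."""
    c = min(max_range_km / EARTH_RADIUS_KM, np.pi * 0.999)
    return 2.0 * EARTH_RADIUS_KM * np.sin(c / 2.0)


def _simulate_individual(rng, spec: PopulationSpec, times: pd.DatetimeIndex):
    """Positions (lon, lat arrays) for one individual over the schedule."""
    proj_colony = AzimuthalEqualArea(spec.colony_lon, spec.colony_lat)
    proj_winter = AzimuthalEqualArea(spec.wintering_lon, spec.wintering_lat)
    r_cap = _plane_cap_radius(spec.max_foraging_range_km)
    dt = spec.sampling_interval_h

    # breeding-trip state (colony plane)
    pos_b = np.zeros(2)
    target = None
    # wintering state (winter plane): mean-reverting walk, tau = 10 days
    a = float(np.exp(-dt / (24.0 * 10.0)))
    pos_w = spec.winter_spread_km * rng.standard_normal(2)

    lons = np.empty(len(times))
    lats = np.empty(len(times))
    months = times.month.to_numpy()
    for i in range(len(times)):
        breeding = months[i] in spec.breeding_months
        if breeding:
            if target is None:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                rho = rng.uniform(0.2, 0.95) * r_cap
                target = rho * np.array([np.cos(theta), np.sin(theta)])
            step = spec.flight_speed_kmh * dt * rng.uniform(0.3, 1.0)
            to_target = target - pos_b
            dist = np.hypot(*to_target)
            if dist <= step:
                pos_b = target.copy()
                if np.allclose(target, 0.0):
                    target = None  # back at colony; next fix starts a new trip
                else:
                    target = np.zeros(2)  # return leg
            else:
                heading = np.arctan2(to_target[1], to_target[0]) + rng.normal(0.0, 0.6)
                pos_b = pos_b + step * np.array([np.cos(heading), np.sin(heading)])
            rho = np.hypot(*pos_b)
            if rho > r_cap:
                pos_b *= r_cap / rho
            lon, lat = proj_colony.inverse(pos_b[0], pos_b[1])
        else:
            noise_sd = spec.winter_spread_km * np.sqrt(max(1.0 - a * a, 1e-12))
            pos_w = a * pos_w + noise_sd * rng.standard_normal(2)
            lon, lat = proj_winter.inverse(pos_w[0], pos_w[1])
        lons[i] = lon
        lats[i] = lat
    return lons, lats


def _apply_device_error(rng, spec: PopulationSpec, lons, lats):
    n = len(lons)
    err = spec.location_error_sd_km * rng.standard_normal((n, 2))
    if spec.outlier_rate > 0:
        glitch = rng.random(n) < spec.outlier_rate
        bearings = rng.uniform(0, 2 * np.pi, n)
        err[glitch, 0] += spec.outlier_km * np.cos(bearings[glitch])
        err[glitch, 1] += spec.outlier_km * np.sin(bearings[glitch])
    km_per_deg = EARTH_RADIUS_KM * np.pi / 180.0
    lats_out = np.clip(lats + err[:, 1] / km_per_deg, -90.0, 90.0)
    coslat = np.maximum(np.cos(np.radians(lats_out)), 1e-6)
    lons_out = normalize_lon(lons + err[:, 0] / (km_per_deg * coslat))
    return lons_out, lats_out


def simulate_population_tracks(
    world: SyntheticWorld, spec: PopulationSpec, seed: int
) -> pd.DataFrame:
    """Simulate a standard-schema tracking table for one population.

    Breeding-month fixes come from out-and-back central-place trips whose
    true positions never exceed the maximum foraging range from the
    colony; non-breeding fixes cluster round the wintering centroid.
    Device error (and optional glitch outliers) are injected afterwards.
    """
    spec.validate()
    if not _colony_has_ocean(world, spec.colony_lon, spec.colony_lat):
        raise GenerationError(
            f"colony of {spec.population_id!r} is on land with no ocean neighbour"
        )
    pop_key = zlib.crc32(spec.population_id.encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, pop_key]))
    tracked = spec.tracked_months or frozenset(range(1, 13))
    times = pd.date_range(
        start=f"{spec.year}-01-01",
        end=f"{spec.year}-12-31 23:59",
        freq=f"{spec.sampling_interval_h}h",
        tz="UTC",
    )
    times = times[times.month.isin(sorted(tracked))]
    frames = []
    for k in range(spec.n_individuals):
        ind_times = times
        if spec.sparse_month is not None:
            in_sparse = ind_times.month == spec.sparse_month
            if k == 0:
                keep = ~in_sparse
                keep[np.flatnonzero(in_sparse)[: spec.sparse_keep]] = True
                ind_times = ind_times[keep]
            else:
                ind_times = ind_times[~in_sparse]
        lons, lats = _simulate_individual(rng, spec, ind_times)
        lons, lats = _apply_device_error(rng, spec, lons, lats)
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": f"{spec.population_id}_{spec.device}",
                    "individual_id": f"{spec.population_id}_ind{k:03d}",
                    "species": spec.species_id,
                    "population": spec.population_id,
                    "colony_lat": spec.colony_lat,
                    "colony_lon": spec.colony_lon,
                    "device": spec.device,
                    "date_time": ind_times,
                    "latitude": lats,
                    "longitude": lons,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]
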