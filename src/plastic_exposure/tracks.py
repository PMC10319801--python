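"""Reading, standardising and quality-filtering seabird tracking data.

Tracking tables are pandas DataFrames with one row per location and the
columns of :data:`TRACK_COLUMNS` (the interchange CSV schema). Three device
types are supported: GPS and PTT (satellite) fixes, which get speed and
colony-buffer filtering plus temporal regularisation, and GLS (light-based
geolocator) fixes, which instead get equinox stripping because light-based
latitudes are unreliable around the equinoxes.

The canonical preprocessing order is: standardise -> equinox strip ->
speed filter -> colony buffer -> resample. The colony buffer is re-applied
after resampling so that every retained point satisfies every filter
predicate simultaneously and the pipeline is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import great_circle_km, normalize_lon, validate_lonlat

logger = logging.getLogger(__name__)

DEVICES = ("GPS", "PTT", "GLS")
IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")

TRACK_COLUMNS = [
    "dataset_id",
    "individual_id",
    "species",
    "population",
    "colony_lat",
    "colony_lon",
    "device",
    "date_time",
    "latitude",
    "longitude",
]


@dataclass(frozen=True)
class ColonyRecord:
    """Metadata for one breeding population / colony."""

    population_id: str
    species_id: str
    colony_lon: float
    colony_lat: float
    breeding_country: str = ""
    population_size: int | None = None  # breeding pairs
    iucn_category: str = "LC"
    equinox_prefiltered: bool = False

    def __post_init__(self):
        validate_lonlat(self.colony_lon, self.colony_lat)
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_category!r}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds for the location-quality filters.

    speed_max : km/h, fixes implying a faster travel speed are dropped
        (GPS/PTT only; strict inequality).
    colony_buffer_km : per-device radius around the colony inside which
        fixes are discarded as colony attendance rather than at-sea use.
    resample_interval_h : target interval of the temporal regularisation
        of GPS/PTT tracks (two locations per day matches GLS resolution).
    equinox_windows : (days before, days after) each equinox inside which
        GLS fixes are dropped.
    min_locations_per_month : pooled monthly sample size below which a
        population-month is excluded downstream.
    """

    speed_max: float = 90.0
    colony_buffer_km: dict = field(
        default_factory=lambda: {"GPS": 5.0, "PTT": 15.0, "GLS": 0.0}
    )
    resample_interval_h: float = 12.0
    march_equinox_window: tuple[int, int] = (21, 7)
    september_equinox_window: tuple[int, int] = (7, 21)
    min_locations_per_month: int = 5

    def __post_init__(self):
        if self.speed_max < 0 or self.resample_interval_h <= 0:
            raise ValueError("thresholds must be non-negative")
        if any(v < 0 for v in self.colony_buffer_km.values()):
            raise ValueError("colony buffers must be non-negative")


# --- I/O -------------------------------------------------------------------


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date_time"])
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    if df["date_time"].dt.tz is None:
        df["date_time"] = df["date_time"].dt.tz_localize("UTC")
    return df


def write_tracks_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date_time"] = pd.to_datetime(out["date_time"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out[TRACK_COLUMNS].to_csv(path, index=False)


def read_colonies_csv(path) -> dict[str, ColonyRecord]:
    df = pd.read_csv(path)
    records = {}
    for row in df.itertuples(index=False):
        size = getattr(row, "population_size", None)
        size = None if size is None or pd.isna(size) else int(size)
        records[str(row.population_id)] = ColonyRecord(
            population_id=str(row.population_id),
            species_id=str(row.species_id),
            colony_lon=float(row.colony_lon),
            colony_lat=float(row.colony_lat),
            breeding_country=str(getattr(row, "breeding_country", "")),
            population_size=size,
            iucn_category=str(getattr(row, "iucn_category", "LC")),
            equinox_prefiltered=bool(getattr(row, "equinox_prefiltered", False)),
        )
    return records


def write_colonies_csv(colonies: dict[str, ColonyRecord], path) -> None:
    pd.DataFrame([vars(c) for c in colonies.values()]).to_csv(path, index=False)


# --- filters ---------------------------------------------------------------


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Validate coordinates, normalise longitudes, sort per individual by
    time, and drop duplicate timestamps (first occurrence kept)."""
    df = df.copy()
    if not df["device"].isin(DEVICES).all():
        raise ValueError("unknown device type present")
    validate_lonlat(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    df["longitude"] = normalize_lon(df["longitude"].to_numpy())
    df["date_time"] = pd.to_datetime(df["date_time"], utc=True)
    df = df.sort_values(["individual_id", "date_time"], kind="stable")
    df = df.drop_duplicates(subset=["individual_id", "date_time"], keep="first")
    return df.reset_index(drop=True)


def _equinox_mask(ts: pd.Series, cfg: PreprocessConfig) -> np.ndarray:
    """True where a timestamp falls inside an equinox exclusion window.

    Equinox instants are taken as 20 March and 22 September, UTC midnight;
    window widths dwarf the +-1 day astronomical drift.
    """
    t = pd.to_datetime(ts, utc=True)
    years = t.dt.year
    inside = np.zeros(len(t), dtype=bool)
    mb, ma = cfg.march_equinox_window
    sb, sa = cfg.september_equinox_window
    for year in years.unique():
        march = pd.Timestamp(year=year, month=3, day=20, tz="UTC")
        sept = pd.Timestamp(year=year, month=9, day=22, tz="UTC")
        inside |= (
            (t >= march - pd.Timedelta(days=mb)) & (t <= march + pd.Timedelta(days=ma))
        ).to_numpy()
        inside |= (
            (t >= sept - pd.Timedelta(days=sb)) & (t <= sept + pd.Timedelta(days=sa))
        ).to_numpy()
    return inside


def strip_equinox(
    df: pd.DataFrame, cfg: PreprocessConfig, prefiltered: bool = False
) -> pd.DataFrame:
    """Drop GLS fixes inside the equinox windows (inclusive endpoints).

    No-op when the geolocator latitudes were already corrected upstream
    (e.g. with sea-surface temperature), or for GPS/PTT rows.
    """
    if prefiltered:
        return df.copy()
    gls = (df["device"] == "GLS").to_numpy()
    drop = gls & _equinox_mask(df["date_time"], cfg)
    return df.loc[~drop].reset_index(drop=True)


def filter_speed(df: pd.DataFrame, speed_max: float = 90.0) -> pd.DataFrame:
    """Iterative forward speed filter for GPS/PTT tracks.

    Per individual, a fix whose implied speed from the previous *retained*
    fix strictly exceeds ``speed_max`` km/h is dropped; the next fix is then
    tested against the last retained one. GLS fixes pass through untouched.
    """
    keep = np.ones(len(df), dtype=bool)
    for _, idx in df.groupby("individual_id", sort=False).indices.items():
        sub = df.iloc[idx]
        if (sub["device"] == "GLS").all():
            continue
        lon = sub["longitude"].to_numpy()
        lat = sub["latitude"].to_numpy()
        t = pd.to_datetime(sub["date_time"], utc=True).astype("int64").to_numpy() / 3.6e12
        last = 0
        for i in range(1, len(sub)):
            dt = t[i] - t[last]
            if dt <= 0:
                keep[idx[i]] = False
                continue
            speed = great_circle_km(lon[last], lat[last], lon[i], lat[i]) / dt
            if speed > speed_max:
                keep[idx[i]] = False
            else:
                last = i
    return df.loc[keep].reset_index(drop=True)


def trim_colony_buffer(
    df: pd.DataFrame, colony: ColonyRecord, buffers: dict | None = None
) -> pd.DataFrame:
    """Drop fixes within the per-device buffer radius of the colony.

    GLS fixes are never trimmed (their location error exceeds any sensible
    buffer); the comparison is strict (< buffer)."""
    buffers = buffers or PreprocessConfig().colony_buffer_km
    dist = great_circle_km(
        df["longitude"].to_numpy(),
        df["latitude"].to_numpy(),
        colony.colony_lon,
        colony.colony_lat,
    )
    radius = df["device"].map(lambda d: buffers.get(d, 0.0)).to_numpy(dtype=float)
    return df.loc[~(dist < radius)].reset_index(drop=True)


def _resample_individual(sub: pd.DataFrame, interval_h: float) -> pd.DataFrame | None:
    if len(sub) < 2:
        logger.warning(
            "dropping single-point track for individual %s", sub["individual_id"].iloc[0]
        )
        return None
    t = pd.to_datetime(sub["date_time"], utc=True).astype("int64").to_numpy() / 3.6e12
    n_out = int(np.floor((t[-1] - t[0]) / interval_h)) + 1
    t_out = t[0] + interval_h * np.arange(n_out)
    # unwrap longitudes so linear interpolation crosses the antimeridian
    lon = np.unwrap(sub["longitude"].to_numpy(), period=360.0)
    lat = sub["latitude"].to_numpy()
    out = sub.iloc[np.searchsorted(t, t_out, side="left").clip(0, len(sub) - 1)].copy()
    out["longitude"] = normalize_lon(np.interp(t_out, t, lon))
    out["latitude"] = np.interp(t_out, t, lat)
    out["date_time"] = pd.to_datetime((t_out * 3.6e12).round().astype("int64"), utc=True)
    return out


def resample_track(df: pd.DataFrame, interval_h: float = 12.0) -> pd.DataFrame:
    """Linearly interpolate and regularise GPS/PTT tracks to a fixed
    interval, anchored at each individual's first retained fix.

    Never extrapolates beyond the first/last observed instant. GLS tracks
    pass through unresampled (they already are at ~2 fixes/day). Tracks
    with fewer than 2 fixes are dropped with a logged warning.
    """
    pieces = []
    for _, sub in df.groupby("individual_id", sort=False):
        if (sub["device"] == "GLS").all():
            pieces.append(sub)
            continue
        res = _resample_individual(sub, interval_h)
        if res is not None:
            pieces.append(res)
    if not pieces:
        return df.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)


def preprocess_population(
    df: pd.DataFrame, colony: ColonyRecord, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Full filter chain for one population's raw tracking table."""
    cfg = cfg or PreprocessConfig()
    df = standardize(df)
    df = strip_equinox(df, cfg, prefiltered=colony.equinox_prefiltered)
    df = filter_speed(df, cfg.speed_max)
    df = trim_colony_buffer(df, colony, cfg.colony_buffer_km)
    df = resample_track(df, cfg.resample_interval_h)
    # interpolation may place points back inside the buffer; enforce the
    # predicate once more so all filters hold simultaneously
    df = trim_colony_buffer(df, colony, cfg.colony_buffer_km)
    return df


def preprocess_tracks(
    df: pd.DataFrame,
    colonies: dict[str, ColonyRecord],
    cfg: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Apply :func:`preprocess_population` per population and concatenate."""
    pieces = []
    for pop, sub in df.groupby("population", sort=False):
        if pop not in colonies:
            raise KeyError(f"no colony record for population {pop!r}")
        pieces.append(preprocess_population(sub, colonies[pop], cfg))
    if not pieces:
        return df.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)
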