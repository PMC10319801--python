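"""Spherical geometry: great-circle distance, spherical centroid, and the
Lambert azimuthal equal-area (LAEA) projection used for kernel density
estimation in planar kilometre coordinates.

All operations assume a spherical Earth of radius 6371 km. Longitudes are
stored normalised to [-180, 180); latitudes in [-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


class CoordinateError(ValueError):
    """Raised when a coordinate falls outside valid lon/lat bounds."""


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def validate_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise CoordinateError("non-finite coordinate")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise CoordinateError("latitude outside [-90, 90]")
    if np.any(lon < -360.0) or np.any(lon >= 360.0):
        raise CoordinateError("longitude outside [-360, 360)")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in kilometres.

    Symmetric, non-negative, zero iff the points coincide. Accepts scalars
    or broadcastable arrays.
    """
    validate_lonlat(lon1, lat1)
    validate_lonlat(lon2, lat2)
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float))
                      for v in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def spherical_centroid(lon, lat) -> tuple[float, float]:
    """Normalised mean of unit vectors on the sphere ("geometric mean" of
    locations in the home-range-analysis sense).

    Falls back to the first point when the mean vector is degenerate
    (antipodally symmetric input).
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("spherical_centroid requires at least one point")
    validate_lonlat(lon, lat)
    lam = np.radians(lon)
    phi = np.radians(lat)
    x = np.mean(np.cos(phi) * np.cos(lam))
    y = np.mean(np.cos(phi) * np.sin(lam))
    z = np.mean(np.sin(phi))
    norm = np.sqrt(x * x + y * y + z * z)
    if norm < 1e-12:
        return float(normalize_lon(lon[0])), float(lat[0])
    return (
        float(normalize_lon(np.degrees(np.arctan2(y, x)))),
        float(np.degrees(np.arcsin(np.clip(z / norm, -1.0, 1.0)))),
    )


@dataclass(frozen=True)
class AzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection centred at
    (center_lon, center_lat), in kilometres.

    Equal-area is required so that kernel densities evaluated per planar
    cell convert to probability mass by a constant cell area.
    """

    center_lon: float
    center_lat: float

    def __post_init__(self):
        validate_lonlat(self.center_lon, self.center_lat)

    def forward(self, lon, lat):
        """lon/lat degrees -> (x, y) km."""
        validate_lonlat(lon, lat)
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - lam0
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        # the antipode maps to infinity; clamp to avoid division blow-up
        denom = np.maximum(denom, 1e-12)
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        rho = np.sqrt(x * x + y * y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        sinc, cosc = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.arcsin(np.clip(
                cosc * np.sin(phi0) + np.where(rho > 0, y * sinc * np.cos(phi0) / rho, 0.0),
                -1.0, 1.0))
            lam = lam0 + np.arctan2(
                x * sinc,
                rho * np.cos(phi0) * cosc - y * np.sin(phi0) * sinc,
            )
        lam = np.where(rho > 0, lam, lam0)
        phi = np.where(rho > 0, phi, phi0)
        lon = normalize_lon(np.degrees(lam))
        lat = np.degrees(phi)
        if np.ndim(lon) == 0:
            return float(lon), float(lat)
        return lon, lat
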