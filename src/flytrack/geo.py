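"""Geographic primitives: points and great-circle arithmetic.

Latitude/longitude are decimal degrees, south and west negative.  All
great-circle math assumes a sphere of radius 6,371 km, the convention of
the downstream migration-distance calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def normalize_lon(lon):
    """Wrap longitude into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = -(np.mod(-lon + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class GeoPoint:
    """A point on the globe (decimal degrees, south/west negative)."""

    lat: float
    lon: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", normalize_lon(self.lon))

    def __iter__(self):
        return iter((self.lat, self.lon))


def great_circle_km(a, b) -> float:
    """Great-circle distance in km between two points (haversine form).

    Accepts ``GeoPoint`` or any (lat, lon) pair.  Symmetric, zero iff the
    points coincide.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def great_circle_km_vec(lat1, lon1, lat2, lon2):
    """Vectorised haversine distance in km (numpy arrays, degrees)."""
    phi1 = np.radians(lat1)
    phi2 = np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def intermediate_point(a, b, frac: float) -> GeoPoint:
    """Point a fraction ``frac`` of the way from ``a`` to ``b`` along the
    great circle (spherical linear interpolation)."""
    lat1, lon1 = a
    lat2, lon2 = b
    phi1, lam1 = math.radians(lat1), math.radians(lon1)
    phi2, lam2 = math.radians(lat2), math.radians(lon2)
    d = great_circle_km(a, b) / EARTH_RADIUS_KM
    if d < 1e-12:
        return GeoPoint(lat1, lon1)
    sa = math.sin((1.0 - frac) * d) / math.sin(d)
    sb = math.sin(frac * d) / math.sin(d)
    x = sa * math.cos(phi1) * math.cos(lam1) + sb * math.cos(phi2) * math.cos(lam2)
    y = sa * math.cos(phi1) * math.sin(lam1) + sb * math.cos(phi2) * math.sin(lam2)
    z = sa * math.sin(phi1) + sb * math.sin(phi2)
    lat = math.degrees(math.atan2(z, math.hypot(x, y)))
    lon = math.degrees(math.atan2(y, x))
    return GeoPoint(lat, lon)
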