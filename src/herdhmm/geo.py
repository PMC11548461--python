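"""Spherical-earth geometry helpers.

Distances use the haversine formula on a sphere of radius 6,371 km; at the
sub-kilometre scale of 30-min cattle steps the difference from a full WGS84
geodesic is far below GPS noise.  Planar work (track simulation, centroids,
rotation-invariant step geometry) goes through a local azimuthal equidistant
frame centred on a reference point, where x is metres east and y metres north.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between points in decimal degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2, radians.

    0 = north, increasing clockwise (eastward), in (-pi, pi].
    """
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.arctan2(y, x)


def wrap_angle(theta) -> np.ndarray:
    """Wrap angles to the half-open interval (-pi, pi]; ties map to +pi."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return out


class LocalProjection:
    """Azimuthal equidistant projection centred on (lat0, lon0).

    Forward maps WGS84 degrees to (x, y) metres; distances from the centre
    and azimuths at the centre are preserved exactly, which is what a
    step-length-true simulation frame needs.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._p0 = np.radians(lat0)

    def forward(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        c = haversine_m(self.lat0, self.lon0, lat, lon) / EARTH_RADIUS_M
        az = initial_bearing_rad(self.lat0, self.lon0, lat, lon)
        r = c * EARTH_RADIUS_M
        return r * np.sin(az), r * np.cos(az)

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        c = r / EARTH_RADIUS_M
        az = np.arctan2(x, y)
        sin_c, cos_c = np.sin(c), np.cos(c)
        p0 = self._p0
        lat = np.arcsin(np.sin(p0) * cos_c + np.cos(p0) * sin_c * np.cos(az))
        lon = np.radians(self.lon0) + np.arctan2(
            np.sin(az) * sin_c * np.cos(p0), cos_c - np.sin(p0) * np.sin(lat)
        )
        with np.errstate(invalid="ignore"):
            lat = np.where(r == 0.0, self._p0, lat)
            lon = np.where(r == 0.0, np.radians(self.lon0), lon)
        return np.degrees(lat), np.degrees(wrap_angle(lon))
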