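"""Great-circle geometry shared across the package.

All positions are WGS-84 latitude/longitude in decimal degrees; bearings are
degrees clockwise from true north; distances are kilometres on a spherical
Earth (mean radius). A spherical Earth is accurate to ~0.5% over the ≤300 km
scales handled here.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points (vectorized, degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle azimuth from point 1 to point 2, degrees in [0, 360)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached from (lat, lon) travelling `distance_km` on `bearing_deg`."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(d) * np.cos(lat1),
        np.cos(d) - np.sin(lat1) * np.sin(lat2),
    )
    return np.degrees(lat2), wrap_lon(np.degrees(lon2))


def wrap_lon(lon):
    """Wrap longitude to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_angle_rad(angle):
    """Wrap an angle in radians to (-pi, pi]."""
    a = np.mod(-np.asarray(angle, dtype=float) + np.pi, 2.0 * np.pi)
    return -(a - np.pi)


def wrap_angle_deg180(angle):
    """Wrap an angle in degrees to (-180, 180]."""
    return np.degrees(wrap_angle_rad(np.radians(angle)))


def latlon_to_ecef(lat, lon):
    """Unit ECEF vectors for lat/lon degrees; shape (..., 3)."""
    latr = np.radians(np.asarray(lat, dtype=float))
    lonr = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(latr) * np.cos(lonr), np.cos(latr) * np.sin(lonr), np.sin(latr)],
        axis=-1,
    )


def ecef_to_latlon(vec):
    """Inverse of :func:`latlon_to_ecef` for unit vectors of shape (..., 3)."""
    v = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / norm
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, wrap_lon(lon)


def rotate_about_axis(vec, axis, angle_deg):
    """Rodrigues rotation of vectors about a unit axis by angle_deg (right-handed)."""
    v = np.asarray(vec, dtype=float)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    theta = np.radians(float(angle_deg))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cross = np.cross(np.broadcast_to(k, v.shape), v)
    dot = v @ k
    return v * cos_t + cross * sin_t + np.outer(dot, k).reshape(v.shape) * (1.0 - cos_t)


def gc_interpolate(lat1, lon1, lat2, lon2, fractions):
    """Points along the great circle from p1 to p2 at `fractions` in [0, 1] (slerp)."""
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    a = latlon_to_ecef(lat1, lon1)
    b = latlon_to_ecef(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        pts = np.tile(a, (f.size, 1))
    else:
        s = np.sin(omega)
        pts = (np.sin((1.0 - f) * omega)[:, None] * a + np.sin(f * omega)[:, None] * b) / s
    lat, lon = ecef_to_latlon(pts)
    return lat, lon
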