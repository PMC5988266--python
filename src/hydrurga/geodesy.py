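"""Spherical-earth geodesy helpers shared across the package.

All distances use the haversine formula on a sphere of radius 6371.0088 km
(the IUGG mean earth radius); one convention everywhere avoids mixed-datum
artefacts when tracks, null models and distance covariates are compared.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Forward azimuth (degrees clockwise from north) from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x))


def destination(lon, lat, bearing_deg, distance_km):
    """Point reached travelling `distance_km` along `bearing_deg` on the sphere."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    sigma = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat) * np.cos(sigma) + np.cos(lat) * np.sin(sigma) * np.cos(brg))
    lon2 = lon + np.arctan2(np.sin(brg) * np.sin(sigma) * np.cos(lat),
                            np.cos(sigma) - np.sin(lat) * np.sin(lat2))
    return wrap_lon(np.degrees(lon2)), np.degrees(lat2)


def gc_interpolate(lon1, lat1, lon2, lat2, frac):
    """Great-circle interpolation between two points.

    `frac` may be an array of fractions in [0, 1]; returns (lon, lat) arrays.
    Coincident endpoints are handled by returning the endpoint itself.
    """
    frac = np.atleast_1d(np.asarray(frac, dtype=float))
    p1 = _unit_vector(lon1, lat1)
    p2 = _unit_vector(lon2, lat2)
    dot = np.clip(np.dot(p1, p2), -1.0, 1.0)
    omega = np.arccos(dot)
    if omega < 1e-12:
        lon = np.full_like(frac, float(lon1))
        lat = np.full_like(frac, float(lat1))
        return lon, lat
    s = np.sin(omega)
    v = (np.sin((1.0 - frac) * omega)[:, None] * p1[None, :]
         + np.sin(frac * omega)[:, None] * p2[None, :]) / s
    lat = np.degrees(np.arcsin(np.clip(v[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return wrap_lon(lon), lat


def _unit_vector(lon, lat):
    lon = np.radians(float(lon))
    lat = np.radians(float(lat))
    return np.array([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)])


def unit_vectors(lon, lat):
    """Vectorized lon/lat (degrees) to 3-D unit vectors, shape (n, 3)."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def chord_to_arc_km(chord):
    """Convert 3-D chord length between unit vectors to great-circle km."""
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))
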