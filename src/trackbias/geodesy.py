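"""Spherical geodesy helpers shared by the simulator and the analysis.

All distances are great-circle (haversine) on a sphere of radius
:data:`EARTH_RADIUS_M`; bearings are initial great-circle bearings in
degrees clockwise from north.  Using one spherical convention everywhere
means the track generator and the bias metrics agree on what "distance"
is, so noise-free round trips are exact.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (m) used for every great-circle computation.
EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (degrees in [0, 360)) from point 1 to 2."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination(lat, lon, bearing_deg, distance_m):
    """Direct geodesic step: point reached from (lat, lon) on the sphere.

    Vectorised over all arguments.
    """
    delta = np.asarray(distance_m) / EARTH_RADIUS_M
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), (np.degrees(lam2) + 540.0) % 360.0 - 180.0


def wrap_angle_deg(angle):
    """Normalise angles (degrees) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def step_bearings_deg(lat, lon):
    """Initial bearing of each step of a polyline: length n-1 for n fixes."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])


def turning_angles_deg(lat, lon):
    """Signed relative turning angle at each interior fix, in (-180, 180].

    For n fixes the result has length n-2: entry i is the change in step
    bearing at fix i+1 (positive = clockwise turn).
    """
    b = step_bearings_deg(lat, lon)
    return wrap_angle_deg(np.diff(b))


def step_distances_m(lat, lon):
    """Great-circle length of each step of a polyline (length n-1)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])


def project_azimuthal_equidistant(lat, lon, lat0, lon0):
    """Project lon/lat to planar metres, azimuthal equidistant about (lat0, lon0).

    Distances from the centre are exact great-circle distances; used for
    kernel density estimation where a locally metric plane is needed.
    Returns (x, y) arrays in metres (x east, y north).
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    phi0 = np.radians(lat0)
    lam0 = np.radians(lon0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k -> 1 as c -> 0 (centre of projection)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y
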