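"""Planar projection of geographic coordinates.

All downstream geometry (ellipse construction, buffers, hulls) assumes
Euclidean coordinates in meters, so geographic fixes are projected to the
UTM zone of the data's centroid by default. The forward Transverse
Mercator mapping is computed from the standard WGS84 series expansion;
its error is sub-millimeter well beyond a single zone's width, which is
negligible against GPS positional error.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)          # first eccentricity squared
_EP2 = _E2 / (1.0 - _E2)       # second eccentricity squared
_K0 = 0.9996                   # UTM scale factor


def utm_zone(lon: float, lat: float) -> tuple[int, bool]:
    """Return (zone number, northern hemisphere flag) for a point."""
    zone = int((lon + 180.0) // 6.0) + 1
    zone = min(max(zone, 1), 60)
    return zone, lat >= 0.0


def utm_forward(
    lon: np.ndarray,
    lat: np.ndarray,
    zone: int,
    north: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to UTM easting/northing (meters).

    Series form of the Transverse Mercator projection on the WGS84
    ellipsoid (meridian-arc expansion to the sixth order in
    eccentricity).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam0 = np.radians(-183.0 + 6.0 * zone)
    phi = np.radians(lat)
    lam = np.radians(lon)

    sin_phi = np.sin(phi)
    cos_phi = np.cos(phi)
    tan_phi = np.tan(phi)

    n_rad = _A / np.sqrt(1.0 - _E2 * sin_phi**2)  # prime-vertical radius
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a_ = cos_phi * (lam - lam0)

    e2 = _E2
    e4 = e2 * e2
    e6 = e4 * e2
    # meridian arc length from the equator
    m = _A * (
        (1.0 - e2 / 4.0 - 3.0 * e4 / 64.0 - 5.0 * e6 / 256.0) * phi
        - (3.0 * e2 / 8.0 + 3.0 * e4 / 32.0 + 45.0 * e6 / 1024.0) * np.sin(2.0 * phi)
        + (15.0 * e4 / 256.0 + 45.0 * e6 / 1024.0) * np.sin(4.0 * phi)
        - (35.0 * e6 / 3072.0) * np.sin(6.0 * phi)
    )

    easting = _K0 * n_rad * (
        a_
        + (1.0 - t + c) * a_**3 / 6.0
        + (5.0 - 18.0 * t + t**2 + 72.0 * c - 58.0 * _EP2) * a_**5 / 120.0
    ) + 500000.0

    northing = _K0 * (
        m
        + n_rad * tan_phi * (
            a_**2 / 2.0
            + (5.0 - t + 9.0 * c + 4.0 * c**2) * a_**4 / 24.0
            + (61.0 - 58.0 * t + t**2 + 600.0 * c - 330.0 * _EP2) * a_**6 / 720.0
        )
    )
    if not north:
        northing = northing + 10000000.0
    return easting, northing


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, zone: int | None = None
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Project to the UTM zone of the centroid (or a given zone).

    Returns (x, y, zone, north). A single zone is used for the whole
    data set so that all individuals share one planar frame.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size == 0:
        raise ValueError("no coordinates to project")
    if zone is None:
        zone, north = utm_zone(float(np.mean(lon)), float(np.mean(lat)))
    else:
        north = float(np.mean(lat)) >= 0.0
    x, y = utm_forward(lon, lat, zone, north)
    return x, y, zone, north
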