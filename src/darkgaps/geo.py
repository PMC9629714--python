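"""Great-circle geometry on a sphere of radius 6371 km (WGS84 degrees in,
kilometres or nautical miles out)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_NMI = 1.852


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; broadcasts over array inputs."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_nmi(lon1, lat1, lon2, lat2):
    return haversine_km(lon1, lat1, lon2, lat2) / KM_PER_NMI


def km_to_nmi(km):
    return np.asarray(km, dtype=float) / KM_PER_NMI


def _to_xyz(lon, lat):
    lon, lat = np.radians(lon), np.radians(lat)
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _to_lonlat(xyz):
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    return np.degrees(np.arctan2(y, x)), np.degrees(np.arcsin(np.clip(z, -1, 1)))


def is_antipodal(lon1, lat1, lon2, lat2, tol_rad: float = 1e-9) -> bool:
    """True when the two points are (numerically) antipodal, so the great
    circle between them is undefined."""
    d = haversine_km(lon1, lat1, lon2, lat2) / EARTH_RADIUS_KM
    return bool(d >= np.pi - tol_rad)


def great_circle_points(lon1, lat1, lon2, lat2, n: int):
    """``n`` points evenly spaced along the minor great-circle arc from
    (lon1, lat1) to (lon2, lat2), endpoints included (spherical linear
    interpolation).  Raises for antipodal endpoints."""
    if n < 2:
        raise ValueError("need n >= 2 points")
    p1 = _to_xyz(float(lon1), float(lat1))
    p2 = _to_xyz(float(lon2), float(lat2))
    cosang = float(np.clip(np.dot(p1, p2), -1.0, 1.0))
    ang = np.arccos(cosang)
    t = np.linspace(0.0, 1.0, n)
    if ang < 1e-12:
        pts = np.repeat(p1[None, :], n, axis=0)
    else:
        if ang >= np.pi - 1e-9:
            raise ValueError("antipodal endpoints: great circle undefined")
        s = np.sin(ang)
        pts = (np.sin((1 - t) * ang)[:, None] * p1
               + np.sin(t * ang)[:, None] * p2) / s
    return _to_lonlat(pts)
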