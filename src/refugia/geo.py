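"""Great-circle geometry on lon/lat coordinates (WGS84 sphere)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays. Raises ``ValueError`` on
    coordinates outside [-180, 180] x [-90, 90].
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
            raise ValueError("coordinates out of range: lon in [-180, 180], lat in [-90, 90]")
    rlon1, rlat1, rlon2, rlat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(rlat1) * np.cos(rlat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def pairwise_km(lons, lats):
    """Symmetric matrix of great-circle distances among points (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def euclidean_degree_distance(lon1, lat1, lon2, lat2):
    """Planar distance in degrees; sensitivity-check alternative to haversine."""
    return np.hypot(np.asarray(lon2, float) - lon1, np.asarray(lat2, float) - lat1)
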