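"""Spherical-earth geometry helpers.

Buffers and areas quoted in kilometres on a geographic grid need an
equal-area computation; distances need great circles. Both are done on
the authalic sphere (R = 6371.0088 km): a local Lambert azimuthal
equal-area frame per species for buffering/area, and haversine
distances for dispersal reach.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of latitude on the authalic sphere
KM_PER_DEG_LAT = 111.195

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG_LAT",
    "haversine_km",
    "sphere_xyz",
    "LocalEqualArea",
]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; arguments broadcast (degrees)."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def sphere_xyz(lon, lat) -> np.ndarray:
    """Unit-sphere Cartesian coordinates, shape (..., 3).

    Chord length c between two unit vectors maps back to great-circle
    distance via d = 2 R asin(c / 2); used with a KD-tree for fast
    nearest-presence queries.
    """
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


class LocalEqualArea:
    """Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Forward-projects lon/lat degrees to x/y kilometres. Areas of
    projected geometries are true sphere areas (km^2); shape distortion
    grows with distance from the centre, which is why each species gets
    its own frame centred on its records.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._sin0 = np.sin(np.deg2rad(lat0))
        self._cos0 = np.cos(np.deg2rad(lat0))

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lam = np.deg2rad(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.deg2rad(np.asarray(lat, dtype=float))
        sinp, cosp = np.sin(phi), np.cos(phi)
        denom = 1.0 + self._sin0 * sinp + self._cos0 * cosp * np.cos(lam)
        # antipode maps to infinity; clip for numerical safety
        k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
        x = EARTH_RADIUS_KM * k * cosp * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (self._cos0 * sinp - self._sin0 * cosp * np.cos(lam))
        return x, y

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """Project a shapely geometry into the local km frame."""
        return shapely.transform(
            geom,
            lambda coords: np.column_stack(self.forward(coords[:, 0], coords[:, 1])),
        )
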