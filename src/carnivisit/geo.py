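"""Geodesic helpers on the WGS84 mean-radius sphere.

All distances are in metres, all coordinates in decimal degrees (WGS84
lon/lat). At the sub-kilometre scales this package works at (100 m dedup
radius, ~1 km grid cells) the mean-radius sphere is accurate to well under
a metre relative to the full ellipsoid, which is immaterial for the
analysis.
"""

from __future__ import annotations

import math

import numpy as np
from shapely import ops
from shapely.geometry.base import BaseGeometry

#: WGS84 mean Earth radius (m).
EARTH_RADIUS_M = 6371008.8


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class LocalProjection:
    """Equirectangular projection centred on (lon0, lat0), metres.

    Locally metric: x = R cos(lat0) dlon, y = R dlat. Adequate for
    distance/area computation over extents of a few tens of kilometres.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._kx = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * math.pi / 180.0
        self._ky = EARTH_RADIUS_M * math.pi / 180.0

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon - self.lon0) * self._kx, (lat - self.lat0) * self._ky

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return ops.transform(lambda x, y: self.forward(x, y), geom)


def geometry_area_km2(geom: BaseGeometry) -> float:
    """Area of a lon/lat geometry in km^2 via a centroid-local projection."""
    if geom.is_empty:
        return 0.0
    c = geom.centroid
    proj = LocalProjection(c.x, c.y)
    return proj.project_geometry(geom).area / 1e6
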