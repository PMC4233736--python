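"""Great-circle geodesy primitives on a spherical Earth.

The default Earth radius is the equatorial value 6378.1 km, which this
package uses throughout (see docs/methods.md); it is configurable via
:class:`EarthModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6378.1


@dataclass(frozen=True)
class EarthModel:
    """Spherical Earth of radius ``radius_km``."""

    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("radius_km must be > 0")

    @property
    def radius_m(self) -> float:
        return self.radius_km * 1000.0


def great_circle_distance(p1, p2, earth: EarthModel = EarthModel()):
    """Haversine distance in km between ``(lon, lat)`` points in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1 = np.radians(np.asarray(p1[0], float)), np.radians(np.asarray(p1[1], float))
    lon2, lat2 = np.radians(np.asarray(p2[0], float)), np.radians(np.asarray(p2[1], float))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    d = 2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing(p1, p2):
    """Forward azimuth (degrees clockwise from north, in [0, 360)) of the
    great circle from ``p1`` to ``p2``, both ``(lon, lat)`` in degrees.

    Undefined (raises ValueError) for coincident points.
    """
    lon1, lat1 = np.radians(np.asarray(p1[0], float)), np.radians(np.asarray(p1[1], float))
    lon2, lat2 = np.radians(np.asarray(p2[0], float)), np.radians(np.asarray(p2[1], float))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    if np.isscalar(x) or x.ndim == 0:
        if float(x) == 0.0 and float(y) == 0.0:
            raise ValueError("bearing undefined for coincident or antipodal points")
    b = np.degrees(np.arctan2(x, y)) % 360.0
    return b if b.ndim else float(b)


def wrap_lon(lon):
    """Wrap longitudes (degrees) to (-180, 180]."""
    lon = np.asarray(lon, float)
    out = -(np.mod(-lon + 180.0, 360.0) - 180.0)
    return out if out.ndim else float(out)
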