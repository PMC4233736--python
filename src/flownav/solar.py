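"""Solar geometry: civil dusk for scheduling nocturnal departures.

Uses the NOAA low-precision solar-position series (fractional-year
Fourier fits for declination and the equation of time), accurate to well
under a minute for dusk timing at the latitudes relevant here.  Civil
dusk is the evening crossing of solar elevation -6 degrees; departures
in the migration experiments default to one hour after civil dusk.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .errors import NoDuskError


def _fractional_year(doy: float, hour_utc: float) -> float:
    return 2.0 * math.pi / 365.0 * (doy - 1.0 + (hour_utc - 12.0) / 24.0)

def _equation_of_time_min(g: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )

def _declination_rad(g: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def solar_elevation(lon: float, lat: float, time) -> float:
    """Solar elevation angle in degrees at a UTC time and position."""
    t = np.datetime64(time, "ns")
    day = t.astype("datetime64[D]")
    doy = float((day - day.astype("datetime64[Y]")) / np.timedelta64(1, "D")) + 1.0
    hour = float((t - day) / np.timedelta64(1, "h"))
    g = _fractional_year(doy, hour)
    decl = _declination_rad(g)
    tst_min = hour * 60.0 + _equation_of_time_min(g) + 4.0 * lon
    ha = math.radians(tst_min / 4.0 - 180.0)
    lat_r = math.radians(lat)
    cos_zen = math.sin(lat_r) * math.sin(decl) + math.cos(lat_r) * math.cos(decl) * math.cos(ha)
    return 90.0 - math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


def civil_dusk(lon: float, lat: float, date) -> np.datetime64:
    """UTC time of civil dusk (solar elevation crossing -6 degrees while
    setting) on the local solar day starting at the given date.

    Raises :class:`NoDuskError` during polar day or polar night.
    """
    day = np.datetime64(date, "D")
    # search from local solar noon through the following local midnight
    noon_utc_h = 12.0 - lon / 15.0
    hours = noon_utc_h + np.linspace(0.0, 12.0, 145)
    base = day.astype("datetime64[ns]")

    def elev(h):
        return solar_elevation(lon, lat, base + np.timedelta64(int(h * 3.6e12), "ns")) + 6.0

    vals = np.array([elev(h) for h in hours])
    if vals[0] <= 0.0:
        raise NoDuskError("sun already below civil twilight at solar noon (polar night)")
    idx = np.where((vals[:-1] > 0.0) & (vals[1:] <= 0.0))[0]
    if idx.size == 0:
        raise NoDuskError("solar elevation never drops below -6 deg (polar day)")
    h = brentq(elev, hours[idx[0]], hours[idx[0] + 1], xtol=1e-7)
    return base + np.timedelta64(int(round(h * 3.6e12)), "ns")


def departure_after_civil_dusk(lon: float, lat: float, date, offset_h: float = 1.0) -> np.datetime64:
    """Departure timestamp: civil dusk plus ``offset_h`` hours."""
    return civil_dusk(lon, lat, date) + np.timedelta64(int(round(offset_h * 3.6e12)), "ns")
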