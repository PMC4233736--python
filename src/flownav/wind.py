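"""Time-varying gridded horizontal wind fields, and synthetic analogues.

A :class:`GriddedWind` holds eastward/northward wind components on a
regular (time, lat, lon) grid in m/s, in the layout of reanalysis
pressure-level products, and exposes the space-time interpolation
contract the spherical simulations need: velocities are bilinear in
lon/lat and linear in time, and the spatial derivatives fed to the
time-optimal heading equation are the analytic derivatives *of that
interpolant* — internally consistent with the velocities used to move
the animal.

Synthetic wind fields (uniform flow, zonal jets, translating vortices)
have exact analytic values and derivatives everywhere, and can be
sampled onto a grid to emulate a reanalysis file for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import (
    DomainNotCoveredError,
    LevelNotFoundError,
    MissingVariableError,
    OutOfDomainError,
)
from .geodesy import EARTH_RADIUS_KM

_U_NAMES = ("uwnd", "u", "U", "eastward_wind", "u_wind", "U_w", "u10")
_V_NAMES = ("vwnd", "v", "V", "northward_wind", "v_wind", "V_w", "v10")


def to_seconds(time) -> np.ndarray:
    """Convert timestamps (datetime64, ISO strings, pandas Timestamps or
    plain float seconds) to float seconds since the Unix epoch."""
    arr = np.asarray(time)
    if np.issubdtype(arr.dtype, np.number):
        return arr.astype(float)
    return arr.astype("datetime64[ns]").astype("int64") / 1e9


# ---------------------------------------------------------------------------
# gridded winds


@dataclass
class GriddedWind:
    """Gridded eastward (``U``) / northward (``V``) wind in m/s.

    ``lons``/``lats`` are in degrees (ascending), ``times`` are
    datetime64; arrays are shaped (time, lat, lon).
    """

    lons: np.ndarray
    lats: np.ndarray
    times: np.ndarray
    U: np.ndarray
    V: np.ndarray
    level: Optional[float] = None

    def __post_init__(self):
        self.lons = np.asarray(self.lons, float)
        self.lats = np.asarray(self.lats, float)
        self.times = np.asarray(self.times).astype("datetime64[ns]")
        self.U = np.asarray(self.U, float)
        self.V = np.asarray(self.V, float)
        if self.lats[0] > self.lats[-1]:
            self.lats = self.lats[::-1].copy()
            self.U = self.U[:, ::-1, :].copy()
            self.V = self.V[:, ::-1, :].copy()
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.U.shape != shape or self.V.shape != shape:
            raise ValueError(
                f"wind arrays must have shape {shape}, got {self.U.shape}"
            )
        if np.isnan(self.U).any() or np.isnan(self.V).any():
            raise ValueError("wind arrays contain missing values")
        if np.any(np.diff(self.lons) <= 0) or np.any(np.diff(self.lats) <= 0):
            raise ValueError("lon/lat axes must be strictly monotone")
        self._tsec = to_seconds(self.times)

    # -- axis location -----------------------------------------------------

    def _locate(self, axis: np.ndarray, q: np.ndarray, name: str):
        if axis.size == 1:
            return np.zeros_like(q, dtype=int), np.zeros_like(q, dtype=float)
        if np.any(q < axis[0] - 1e-9) or np.any(q > axis[-1] + 1e-9):
            raise OutOfDomainError(
                f"{name} query outside [{axis[0]}, {axis[-1]}]"
            )
        i = np.clip(np.searchsorted(axis, q, side="right") - 1, 0, axis.size - 2)
        w = (q - axis[i]) / (axis[i + 1] - axis[i])
        return i, np.clip(w, 0.0, 1.0)

    def _weights(self, lon, lat, time):
        lon = np.atleast_1d(np.asarray(lon, float))
        lat = np.atleast_1d(np.asarray(lat, float))
        tsec = np.atleast_1d(to_seconds(time))
        lon, lat, tsec = np.broadcast_arrays(lon, lat, tsec)
        i, wx = self._locate(self.lons, lon, "longitude")
        j, wy = self._locate(self.lats, lat, "latitude")
        k, wt = self._locate(self._tsec, tsec, "time")
        return i, wx, j, wy, k, wt

    def _bilinear(self, A, i, wx, j, wy, k):
        a00 = A[k, j, i]
        a01 = A[k, j, i + 1]
        a10 = A[k, j + 1, i]
        a11 = A[k, j + 1, i + 1]
        return (
            (1 - wy) * ((1 - wx) * a00 + wx * a01)
            + wy * ((1 - wx) * a10 + wx * a11)
        )

    def velocity(self, lon, lat, time) -> Tuple[np.ndarray, np.ndarray]:
        """Interpolated ``(U, V)`` in m/s; raises OutOfDomainError outside
        the grid."""
        i, wx, j, wy, k, wt = self._weights(lon, lat, time)
        out = []
        for A in (self.U, self.V):
            v0 = self._bilinear(A, i, wx, j, wy, k)
            if self.times.size > 1:
                v1 = self._bilinear(A, i, wx, j, wy, np.minimum(k + 1, len(self._tsec) - 1))
                out.append((1 - wt) * v0 + wt * v1)
            else:
                out.append(v0)
        u, v = out
        if u.ndim == 0 or u.size == 1:
            return float(np.ravel(u)[0]), float(np.ravel(v)[0])
        return u, v

    def jacobian(self, lon, lat, time):
        """Analytic spatial derivatives of the interpolant, per degree:
        ``(dU/dlon, dU/dlat, dV/dlon, dV/dlat)``.

        Piecewise constant across cells in each direction (the derivative
        of a bilinear patch), linearly interpolated in time.
        """
        i, wx, j, wy, k, wt = self._weights(lon, lat, time)
        dlon = self.lons[i + 1] - self.lons[i] if self.lons.size > 1 else 1.0
        dlat = self.lats[j + 1] - self.lats[j] if self.lats.size > 1 else 1.0

        def partials(A, kk):
            a00, a01 = A[kk, j, i], A[kk, j, i + 1]
            a10, a11 = A[kk, j + 1, i], A[kk, j + 1, i + 1]
            ddx = ((1 - wy) * (a01 - a00) + wy * (a11 - a10)) / dlon
            ddy = ((1 - wx) * (a10 - a00) + wx * (a11 - a01)) / dlat
            return ddx, ddy

        res = []
        for A in (self.U, self.V):
            dx0, dy0 = partials(A, k)
            if self.times.size > 1:
                k1 = np.minimum(k + 1, len(self._tsec) - 1)
                dx1, dy1 = partials(A, k1)
                res.extend(((1 - wt) * dx0 + wt * dx1, (1 - wt) * dy0 + wt * dy1))
            else:
                res.extend((dx0, dy0))
        if res[0].ndim == 0 or res[0].size == 1:
            return tuple(float(np.ravel(r)[0]) for r in res)
        return tuple(res)

    def covers(self, lon, lat, time) -> bool:
        try:
            self._weights(lon, lat, time)
            return True
        except OutOfDomainError:
            return False


# ---------------------------------------------------------------------------
# synthetic analytic wind fields


class WindPrimitive:
    """Base class for analytic wind primitives (value + exact jacobian)."""

    def velocity(self, lon, lat, tsec):
        raise NotImplementedError

    def jacobian(self, lon, lat, tsec):
        raise NotImplementedError


@dataclass(frozen=True)
class UniformWind(WindPrimitive):
    """Spatially uniform wind ``(u, v)`` m/s."""

    u: float
    v: float

    def velocity(self, lon, lat, tsec):
        shape = np.broadcast(lon, lat, tsec).shape
        return np.full(shape, self.u), np.full(shape, self.v)

    def jacobian(self, lon, lat, tsec):
        z = np.zeros(np.broadcast(lon, lat, tsec).shape)
        return z, z.copy(), z.copy(), z.copy()


@dataclass(frozen=True)
class ZonalJet(WindPrimitive):
    """Gaussian zonal jet: eastward wind peaking at ``u_max`` m/s on the
    core latitude, decaying with the e-folding half-width (degrees)."""

    lat0: float
    width_deg: float
    u_max: float

    def velocity(self, lon, lat, tsec):
        lat = np.asarray(lat, float)
        u = self.u_max * np.exp(-(((lat - self.lat0) / self.width_deg) ** 2))
        shape = np.broadcast(lon, lat, tsec).shape
        return np.broadcast_to(u, shape).copy(), np.zeros(shape)

    def jacobian(self, lon, lat, tsec):
        lat = np.asarray(lat, float)
        u = self.u_max * np.exp(-(((lat - self.lat0) / self.width_deg) ** 2))
        du_dlat = u * (-2.0 * (lat - self.lat0) / self.width_deg**2)
        z = np.zeros(np.broadcast(lon, lat, tsec).shape)
        return z, np.broadcast_to(du_dlat, z.shape).copy(), z.copy(), z.copy()


@dataclass(frozen=True)
class TranslatingVortex(WindPrimitive):
    """A smooth vortex whose centre translates linearly in time.

    Tangential speed ``v_max * (r/rc) * exp((1 - (r/rc)^2)/2)`` peaks at
    ``v_max`` on the core radius ``rc`` (km) and decays smoothly outward;
    ``sense=+1`` is counter-clockwise (cyclonic, northern hemisphere).
    The centre starts at ``(lon0, lat0)`` at ``t0`` and moves at
    ``(dlon_per_h, dlat_per_h)`` degrees/hour.  Distances use a local
    tangent plane anchored at the reference latitude ``lat0``.
    """

    lon0: float
    lat0: float
    v_max: float
    core_radius_km: float
    dlon_per_h: float = 0.0
    dlat_per_h: float = 0.0
    t0: object = 0.0
    sense: int = 1

    def _tangent(self, lon, lat, tsec):
        t_h = (np.asarray(tsec, float) - float(to_seconds(self.t0))) / 3600.0
        lon_c = self.lon0 + self.dlon_per_h * t_h
        lat_c = self.lat0 + self.dlat_per_h * t_h
        mx = EARTH_RADIUS_KM * math.cos(math.radians(self.lat0)) * math.pi / 180.0
        my = EARTH_RADIUS_KM * math.pi / 180.0
        dx = (np.asarray(lon, float) - lon_c) * mx  # km east of centre
        dy = (np.asarray(lat, float) - lat_c) * my  # km north of centre
        return dx, dy, mx, my

    def _omega(self, r2):
        rc = self.core_radius_km
        om = self.sense * (self.v_max / rc) * np.exp((1.0 - r2 / rc**2) / 2.0)
        return om, -om / (2.0 * rc**2)

    def velocity(self, lon, lat, tsec):
        dx, dy, _, _ = self._tangent(lon, lat, tsec)
        om, _ = self._omega(dx * dx + dy * dy)
        # tangential (counter-clockwise for sense=+1); dx, dy in km but the
        # km factors cancel in omega * distance -> m/s via v_max scaling
        return -om * dy, om * dx

    def jacobian(self, lon, lat, tsec):
        dx, dy, mx, my = self._tangent(lon, lat, tsec)
        om, dom = self._omega(dx * dx + dy * dy)
        du_dx = -dom * 2.0 * dx * dy
        du_dy = -om - dom * 2.0 * dy * dy
        dv_dx = om + dom * 2.0 * dx * dx
        dv_dy = dom * 2.0 * dx * dy
        return du_dx * mx, du_dy * my, dv_dx * mx, dv_dy * my


@dataclass
class SyntheticWindField:
    """A sum of analytic wind primitives, with exact derivatives.

    Duck-types the :class:`GriddedWind` query interface (``velocity`` /
    ``jacobian`` / ``covers``) so simulations can run directly on the
    analytic field; ``sample`` grids it for file-backed workflows.
    """

    components: List[WindPrimitive]
    level: Optional[float] = None

    def velocity(self, lon, lat, time):
        tsec = to_seconds(time)
        u = v = 0.0
        for c in self.components:
            cu, cv = c.velocity(lon, lat, tsec)
            u, v = u + cu, v + cv
        if np.ndim(u) == 0 or np.size(u) == 1:
            return float(np.ravel(u)[0]), float(np.ravel(v)[0])
        return u, v

    def jacobian(self, lon, lat, time):
        tsec = to_seconds(time)
        acc = [0.0, 0.0, 0.0, 0.0]
        for c in self.components:
            for n, p in enumerate(c.jacobian(lon, lat, tsec)):
                acc[n] = acc[n] + p
        if np.ndim(acc[0]) == 0 or np.size(acc[0]) == 1:
            return tuple(float(np.ravel(a)[0]) for a in acc)
        return tuple(np.asarray(a) for a in acc)

    def covers(self, lon, lat, time) -> bool:
        return True

    def sample(
        self,
        bbox: Tuple[float, float, float, float],
        times,
        resolution_deg: float = 1.0,
    ) -> GriddedWind:
        """Grid the analytic field: bbox = (lon_min, lon_max, lat_min,
        lat_max), ``times`` a sequence of timestamps."""
        lon_min, lon_max, lat_min, lat_max = bbox
        lons = np.arange(lon_min, lon_max + resolution_deg / 2, resolution_deg)
        lats = np.arange(lat_min, lat_max + resolution_deg / 2, resolution_deg)
        times = np.asarray(times).astype("datetime64[ns]")
        LON, LAT = np.meshgrid(lons, lats)
        U = np.empty((len(times), len(lats), len(lons)))
        V = np.empty_like(U)
        for k, t in enumerate(to_seconds(times)):
            u, v = self.velocity(LON, LAT, t)
            U[k] = np.broadcast_to(u, LON.shape)
            V[k] = np.broadcast_to(v, LON.shape)
        return GriddedWind(lons, lats, times, U, V, level=self.level)


def generate_synthetic_wind(
    field: SyntheticWindField,
    bbox: Tuple[float, float, float, float],
    times,
    resolution_deg: float = 1.0,
) -> GriddedWind:
    """Grid a synthetic analytic wind field (see
    :meth:`SyntheticWindField.sample`)."""
    return field.sample(bbox, times, resolution_deg)


# ---------------------------------------------------------------------------
# NetCDF IO (classic NetCDF3 via xarray's scipy backend)


def write_wind_netcdf(wind: GriddedWind, path) -> None:
    """Write a GriddedWind to a NetCDF file with reanalysis-style
    variable names (uwnd/vwnd on lon/lat/time axes)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "uwnd": (("time", "lat", "lon"), wind.U, {"units": "m/s"}),
            "vwnd": (("time", "lat", "lon"), wind.V, {"units": "m/s"}),
        },
        coords={
            "time": wind.times,
            "lat": ("lat", wind.lats, {"units": "degrees_north"}),
            "lon": ("lon", wind.lons, {"units": "degrees_east"}),
        },
    )
    if wind.level is not None:
        ds.attrs["level_mb"] = float(wind.level)
    ds.to_netcdf(path, engine="scipy")


def read_wind_netcdf(
    path,
    level: Optional[float] = None,
    bbox: Optional[Tuple[float, float, float, float]] = None,
    timespan: Optional[Tuple] = None,
    var_map: Optional[dict] = None,
) -> GriddedWind:
    """Read gridded winds from a NetCDF file.

    ``level`` selects a pressure level (mb) when the file has a level
    axis; ``bbox`` = (lon_min, lon_max, lat_min, lat_max) and
    ``timespan`` = (start, end) subset the grid, and must be strictly
    inside the file's domain.  ``var_map`` may name the wind variables
    explicitly, e.g. ``{"u": "UGRD", "v": "VGRD"}``.
    """
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy", decode_timedelta=False)
    try:
        names = {v.lower(): v for v in ds.data_vars}
        if var_map:
            u_name, v_name = var_map["u"], var_map["v"]
        else:
            u_name = next((names[c.lower()] for c in _U_NAMES if c.lower() in names), None)
            v_name = next((names[c.lower()] for c in _V_NAMES if c.lower() in names), None)
        if u_name is None or v_name is None or u_name not in ds or v_name not in ds:
            raise MissingVariableError(
                f"no eastward/northward wind variables found in {path} "
                f"(have {list(ds.data_vars)})"
            )
        da_u, da_v = ds[u_name], ds[v_name]

        lev_dim = next((d for d in da_u.dims if d.lower() in ("level", "lev", "plev")), None)
        if lev_dim is not None:
            levels = ds[lev_dim].values.astype(float)
            if level is None:
                raise LevelNotFoundError(
                    f"file has levels {levels.tolist()}; choose one"
                )
            match = np.where(np.isclose(levels, float(level)))[0]
            if match.size == 0:
                raise LevelNotFoundError(
                    f"level {level} mb not in file levels {levels.tolist()}"
                )
            da_u = da_u.isel({lev_dim: int(match[0])})
            da_v = da_v.isel({lev_dim: int(match[0])})
        lon_dim = next((d for d in da_u.dims if d.lower() in ("lon", "longitude")), None)
        lat_dim = next((d for d in da_u.dims if d.lower() in ("lat", "latitude")), None)
        time_dim = next((d for d in da_u.dims if d.lower() == "time"), None)
        if lon_dim is None or lat_dim is None or time_dim is None:
            raise MissingVariableError(f"wind variables lack lon/lat/time axes in {path}")

        lons = wrap_sorted_lons(ds[lon_dim].values.astype(float))
        da_u = da_u.assign_coords({lon_dim: lons}).sortby([lon_dim, lat_dim])
        da_v = da_v.assign_coords({lon_dim: lons}).sortby([lon_dim, lat_dim])

        if bbox is not None:
            lon_min, lon_max, lat_min, lat_max = bbox
            cl, ca = da_u[lon_dim].values, da_u[lat_dim].values
            if lon_min < cl.min() or lon_max > cl.max() or lat_min < ca.min() or lat_max > ca.max():
                raise DomainNotCoveredError(
                    f"bbox {bbox} not covered by grid lon [{cl.min()}, {cl.max()}], "
                    f"lat [{ca.min()}, {ca.max()}]"
                )
            sel = {lon_dim: slice(lon_min, lon_max), lat_dim: slice(lat_min, lat_max)}
            da_u, da_v = da_u.sel(sel), da_v.sel(sel)
        if timespan is not None:
            t0, t1 = (np.datetime64(t) for t in timespan)
            tv = da_u[time_dim].values
            if t0 < tv.min() or t1 > tv.max():
                raise DomainNotCoveredError(
                    f"timespan {timespan} not covered by file times "
                    f"[{tv.min()}, {tv.max()}]"
                )
            da_u = da_u.sel({time_dim: slice(t0, t1)})
            da_v = da_v.sel({time_dim: slice(t0, t1)})

        da_u = da_u.transpose(time_dim, lat_dim, lon_dim)
        da_v = da_v.transpose(time_dim, lat_dim, lon_dim)
        lvl = level if level is not None else ds.attrs.get("level_mb")
        return GriddedWind(
            lons=da_u[lon_dim].values.astype(float),
            lats=da_u[lat_dim].values.astype(float),
            times=da_u[time_dim].values,
            U=da_u.values.astype(float),
            V=da_v.values.astype(float),
            level=lvl,
        )
    finally:
        ds.close()


def wrap_sorted_lons(lons: np.ndarray) -> np.ndarray:
    """Map a longitude axis to (-180, 180]; returned values are unsorted
    (callers re-sort data along the axis)."""
    out = -(np.mod(-np.asarray(lons, float) + 180.0, 360.0) - 180.0)
    return out
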