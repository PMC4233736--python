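"""Gridded and synthetic wind fields: interpolation contract, analytic
derivatives of the interpolant, and NetCDF round-trips."""

import hashlib

import numpy as np
import pytest

from flownav.errors import (
    DomainNotCoveredError,
    LevelNotFoundError,
    MissingVariableError,
    OutOfDomainError,
)
from flownav.wind import (
    GriddedWind,
    SyntheticWindField,
    TranslatingVortex,
    UniformWind,
    ZonalJet,
    generate_synthetic_wind,
    read_wind_netcdf,
    write_wind_netcdf,
)

T0 = np.datetime64("2006-10-01T00:00")
TIMES = np.arange(T0, T0 + np.timedelta64(30, "h"), np.timedelta64(6, "h"))
BBOX = (-5.0, 15.0, 45.0, 65.0)


@pytest.fixture(scope="module")
def vortex_field():
    return SyntheticWindField(
        [TranslatingVortex(5.0, 55.0, 12.0, 300.0, dlon_per_h=0.1, t0=T0)]
    )


@pytest.fixture(scope="module")
def vortex_grid(vortex_field):
    return generate_synthetic_wind(vortex_field, BBOX, TIMES, 1.0)


class TestInterpolation:
    def test_grid_nodes_reproduced_exactly(self, vortex_grid):
        u, v = vortex_grid.velocity(3.0, 57.0, TIMES[2])
        assert u == vortex_grid.U[2, 12, 8]
        assert v == vortex_grid.V[2, 12, 8]

    def test_cell_midpoint_is_the_bilinear_average(self):
        U = np.zeros((1, 2, 2))
        V = np.zeros((1, 2, 2))
        U[0] = [[0.0, 0.0], [2.0, 2.0]]
        gw = GriddedWind([0.0, 1.0], [0.0, 1.0], [T0], U, V)
        u, v = gw.velocity(0.5, 0.5, T0)
        assert u == pytest.approx(1.0)
        assert v == 0.0

    def test_uniform_field_interpolates_exactly_everywhere(self):
        f = SyntheticWindField([UniformWind(5.0, -3.0)])
        gw = generate_synthetic_wind(f, BBOX, TIMES, 2.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            lon = rng.uniform(-5, 15)
            lat = rng.uniform(45, 65)
            t = TIMES[0] + np.timedelta64(int(rng.uniform(0, 24 * 3600)), "s")
            u, v = gw.velocity(lon, lat, t)
            assert u == pytest.approx(5.0) and v == pytest.approx(-3.0)

    def test_no_extrapolation_outside_domain(self, vortex_grid):
        with pytest.raises(OutOfDomainError):
            vortex_grid.velocity(30.0, 50.0, TIMES[0])
        with pytest.raises(OutOfDomainError):
            vortex_grid.velocity(0.0, 50.0, TIMES[-1] + np.timedelta64(2, "D"))

    def test_interpolant_converges_with_resolution(self, vortex_field):
        rng = np.random.default_rng(1)
        pts = [
            (rng.uniform(-4, 14), rng.uniform(46, 64),
             TIMES[0] + np.timedelta64(int(rng.uniform(0, 24 * 3600)), "s"))
            for _ in range(40)
        ]
        errs = []
        for res in (2.0, 1.0, 0.5):
            gw = generate_synthetic_wind(vortex_field, BBOX, TIMES, res)
            err = 0.0
            for lon, lat, t in pts:
                ui, vi = gw.velocity(lon, lat, t)
                ue, ve = vortex_field.velocity(lon, lat, t)
                err = max(err, abs(ui - ue), abs(vi - ve))
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]


class TestJacobian:
    def test_uniform_flow_partials_are_zero(self):
        f = SyntheticWindField([UniformWind(4.0, 2.0)])
        gw = generate_synthetic_wind(f, BBOX, TIMES, 2.0)
        assert gw.jacobian(3.3, 50.7, TIMES[1]) == pytest.approx((0, 0, 0, 0))

    def test_linear_in_lat_flow_recovers_exact_slope(self):
        lats = np.array([50.0, 52.0, 54.0])
        lons = np.array([0.0, 2.0])
        U = np.tile((3.0 * (lats - 50.0))[None, :, None], (1, 1, 2))
        gw = GriddedWind(lons, lats, [T0], U, np.zeros_like(U))
        jac = gw.jacobian(1.0, 51.3, T0)
        assert jac[1] == pytest.approx(3.0)
        assert jac[0] == jac[2] == jac[3] == 0.0

    def test_jacobian_matches_finite_differences_of_interpolant(self, vortex_grid):
        lon, lat, t = 3.3, 56.7, TIMES[1] + np.timedelta64(90, "m")
        h = 1e-6
        jac = vortex_grid.jacobian(lon, lat, t)
        up, _ = vortex_grid.velocity(lon + h, lat, t)
        um, _ = vortex_grid.velocity(lon - h, lat, t)
        assert (up - um) / (2 * h) == pytest.approx(jac[0], rel=1e-6, abs=1e-10)
        _, vp = vortex_grid.velocity(lon, lat + h, t)
        _, vm = vortex_grid.velocity(lon, lat - h, t)
        assert (vp - vm) / (2 * h) == pytest.approx(jac[3], rel=1e-6, abs=1e-10)

    def test_gridded_partials_near_analytic_away_from_core(self, vortex_field):
        gw = generate_synthetic_wind(vortex_field, (0.0, 10.0, 50.0, 60.0), TIMES, 0.25)
        # centre at t=TIMES[0] is (5, 55); probe cell midpoints (where the
        # piecewise-bilinear derivative is centred) > 1 cell from the core
        for lon, lat in ((7.625, 57.625), (2.625, 52.625), (8.125, 53.125)):
            got = np.array(gw.jacobian(lon, lat, TIMES[0]))
            exact = np.array(vortex_field.jacobian(lon, lat, TIMES[0]))
            scale = np.max(np.abs(exact))
            assert np.all(np.abs(got - exact) <= 0.05 * scale)


class TestSyntheticGeneration:
    def test_uniform_spec_grids_constant_values(self):
        f = SyntheticWindField([UniformWind(5.0, 0.0)])
        gw = generate_synthetic_wind(f, BBOX, TIMES, 2.0)
        assert np.all(gw.U == 5.0) and np.all(gw.V == 0.0)

    def test_vortex_speed_peaks_on_core_radius(self, vortex_field):
        vx = vortex_field.components[0]
        ky = 6378.1 * np.pi / 180.0
        dlat = vx.core_radius_km / ky
        u, v = vortex_field.velocity(5.0, 55.0 + dlat, T0)
        assert np.hypot(u, v) == pytest.approx(12.0, rel=1e-6)
        u, v = vortex_field.velocity(5.0, 55.0, T0)
        assert np.hypot(u, v) == pytest.approx(0.0, abs=1e-9)

    def test_generation_is_deterministic(self, vortex_field):
        a = generate_synthetic_wind(vortex_field, BBOX, TIMES, 1.0)
        b = generate_synthetic_wind(vortex_field, BBOX, TIMES, 1.0)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_zonal_jet_profile(self):
        jet = ZonalJet(lat0=55.0, width_deg=5.0, u_max=20.0)
        u, v = jet.velocity(0.0, 55.0, 0.0)
        assert float(u) == pytest.approx(20.0) and float(v) == 0.0
        u, _ = jet.velocity(0.0, 60.0, 0.0)
        assert float(u) == pytest.approx(20.0 * np.exp(-1.0))


class TestNetCDF:
    def test_round_trip_preserves_arrays(self, vortex_grid, tmp_path):
        p = tmp_path / "wind.nc"
        write_wind_netcdf(vortex_grid, p)
        back = read_wind_netcdf(p)
        assert np.allclose(back.U, vortex_grid.U)
        assert np.allclose(back.V, vortex_grid.V)
        assert np.array_equal(
            back.times.astype("datetime64[s]"),
            vortex_grid.times.astype("datetime64[s]"),
        )

    def test_write_is_deterministic(self, vortex_grid, tmp_path):
        p1, p2 = tmp_path / "a.nc", tmp_path / "b.nc"
        write_wind_netcdf(vortex_grid, p1)
        write_wind_netcdf(vortex_grid, p2)
        assert hashlib.sha256(p1.read_bytes()).digest() == hashlib.sha256(
            p2.read_bytes()
        ).digest()

    def test_bbox_subset_and_coverage_error(self, vortex_grid, tmp_path):
        p = tmp_path / "wind.nc"
        write_wind_netcdf(vortex_grid, p)
        sub = read_wind_netcdf(p, bbox=(0.0, 10.0, 50.0, 60.0))
        assert sub.lons.min() >= 0.0 and sub.lons.max() <= 10.0
        with pytest.raises(DomainNotCoveredError):
            read_wind_netcdf(p, bbox=(-60.0, 10.0, 50.0, 60.0))

    def test_timespan_not_covered(self, vortex_grid, tmp_path):
        p = tmp_path / "wind.nc"
        write_wind_netcdf(vortex_grid, p)
        with pytest.raises(DomainNotCoveredError):
            read_wind_netcdf(p, timespan=("2006-09-01", "2006-09-02"))

    def test_missing_variable_error(self, tmp_path):
        import xarray as xr

        p = tmp_path / "bad.nc"
        xr.Dataset(
            {"temp": (("time", "lat", "lon"), np.zeros((1, 2, 2)))},
            coords={"time": [T0], "lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        ).to_netcdf(p, engine="scipy")
        with pytest.raises(MissingVariableError):
            read_wind_netcdf(p)

    def test_level_selection(self, tmp_path):
        import xarray as xr

        levels = [1000.0, 925.0, 850.0]
        data = np.zeros((1, 3, 2, 2))
        for i, lev in enumerate(levels):
            data[:, i] = lev
        ds = xr.Dataset(
            {
                "uwnd": (("time", "level", "lat", "lon"), data),
                "vwnd": (("time", "level", "lat", "lon"), np.zeros_like(data)),
            },
            coords={"time": [T0], "level": levels, "lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        )
        p = tmp_path / "levels.nc"
        ds.to_netcdf(p, engine="scipy")
        gw = read_wind_netcdf(p, level=925)
        assert np.all(gw.U == 925.0)
        with pytest.raises(LevelNotFoundError):
            read_wind_netcdf(p, level=700)
        with pytest.raises(LevelNotFoundError):
            read_wind_netcdf(p)
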