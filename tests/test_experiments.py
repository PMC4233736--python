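"""Experiment designs and metrics: efficiency, flow support, events,
sweeps and the seasonal heading optimization."""

import math

import numpy as np
import pytest

from flownav.experiments import (
    MigrationConfig,
    departure_sweep_rotational,
    efficiency,
    flow_support,
    optimize_seasonal_heading,
    run_event,
    sweep_region,
)
from flownav.geodesy import initial_bearing
from flownav.strategies import ShootingConfig
from flownav.wind import SyntheticWindField, TranslatingVortex, UniformWind

START, GOAL = (8.5, 60.0), (6.0, 53.0)
DEP = np.datetime64("2006-10-31T18:00")


def _config(**kw):
    base = dict(
        start=START, goal=GOAL, arrival_radius_km=20.0,
        self_speed=12.0, dt_s=180.0, interval_deg=5.0,
    )
    base.update(kw)
    return MigrationConfig(**base)


def _crosswind(speed, bearing_deg, offset_deg=90.0):
    ang = math.radians(bearing_deg + offset_deg)
    return SyntheticWindField([UniformWind(speed * math.sin(ang), speed * math.cos(ang))])


class TestMetrics:
    def test_efficiency_is_optimal_over_realized_duration(self):
        # strong-wind thrush night: 8.7 h optimal vs 9.0 h vector and
        # 39 h goal orientation
        assert efficiency(9.0, 8.7) == pytest.approx(0.97, abs=0.005)
        assert efficiency(39.0, 8.7) == pytest.approx(0.22, abs=0.005)
        assert efficiency(8.7, 8.7) == 1.0
        assert math.isnan(efficiency(math.nan, 8.7))

    def test_flow_support_sign_conventions(self):
        # still air, direct route
        assert flow_support(1.0, 1.0, 1.0) == 0.0
        # shear crossing is always opposed: duration exceeds still-air
        assert flow_support(1.0, 1.2, 1.0) < 0
        # rotational through-flow with vector orientation is supported
        assert flow_support(2.0, 2 * math.atan(0.8) / 0.8, 1.0) > 0
        assert math.isnan(flow_support(1.0, math.nan, 1.0))


class TestRunEvent:
    def test_uniform_tailwind_equalizes_all_strategies(self):
        b = initial_bearing(START, GOAL)
        wind = _crosswind(6.0, b, offset_deg=0.0)  # pure tailwind
        res = run_event(_config(), wind, DEP)
        durs = [r.duration for r in res.values()]
        assert all(r.arrived for r in res.values())
        assert max(durs) / min(durs) < 1.005
        assert all(r.flow_support > 0.4 for r in res.values())

    def test_uniform_crosswind_vector_equals_fullcomp_goal_slower(self):
        b = initial_bearing(START, GOAL)
        wind = _crosswind(6.0, b)  # half self-speed, purely lateral
        res = run_event(_config(), wind, DEP)
        assert all(r.arrived for r in res.values())
        assert res["vector"].duration == pytest.approx(
            res["fullcomp"].duration, rel=0.005
        )
        assert res["goal"].duration > res["fullcomp"].duration

    def test_weak_crosswind_keeps_every_strategy_near_optimal(self):
        # 0.4x self-speed lateral wind: even goal orientation (whose
        # pursuit-curve duration is D/(1-w^2) against D/sqrt(1-w^2)
        # optimal) stays above 0.9 efficiency
        b = initial_bearing(START, GOAL)
        wind = _crosswind(4.8, b)
        res = run_event(_config(), wind, DEP)
        assert all(r.arrived for r in res.values())
        assert all(r.efficiency >= 0.9 for r in res.values())

    def test_strong_vortex_defeats_full_compensation_not_optimal(self):
        # a cyclone straddling the route with winds 1.5x the self-speed
        wind = SyntheticWindField(
            [TranslatingVortex(7.0, 56.5, 18.0, 250.0, t0=DEP - np.timedelta64(18, "h"))]
        )
        res = run_event(_config(), wind, DEP)
        assert res["optimal"].arrived
        assert not res["fullcomp"].arrived
        assert res["fullcomp"].reason == "infeasible"
        assert res["optimal"].efficiency == 1.0

    def test_efficiencies_never_exceed_optimal(self):
        b = initial_bearing(START, GOAL)
        wind = _crosswind(4.0, b, offset_deg=45.0)
        res = run_event(_config(), wind, DEP)
        for r in res.values():
            if r.arrived:
                assert r.efficiency <= 1.0 + 1e-3


class TestDepartureSweep:
    CFG = ShootingConfig(dt=5e-3, interval_width_deg=5.0, refine_rounds=5)

    def test_region_is_inside_both_circles(self):
        pts = sweep_region(0.05)
        x, y = pts[:, 0], pts[:, 1]
        assert np.all(x >= 0)
        assert np.all(x**2 + y**2 <= 1 + 1e-12)
        assert np.all(x**2 + (y - 1) ** 2 <= 1 + 1e-12)

    def test_still_air_sweep_is_perfect_everywhere(self):
        res = departure_sweep_rotational(0.0, spacing=0.4, config=self.CFG)
        assert all(p == 1.0 for p in res.success_rate.values())
        for q in res.efficiency_quantiles.values():
            assert q[1] == pytest.approx(1.0, abs=2e-3)

    def test_strong_flow_ranking_and_fullcomp_failure(self):
        res = departure_sweep_rotational(1.7, spacing=0.4, config=self.CFG)
        p = res.success_rate
        assert p["fullcomp"] == 0.0
        assert p["optimal"] >= p["vector"] >= p["goal"]

    def test_sweep_is_deterministic(self):
        a = departure_sweep_rotational(0.8, spacing=0.5, config=self.CFG)
        b = departure_sweep_rotational(0.8, spacing=0.5, config=self.CFG)
        assert a.success_rate == b.success_rate
        assert a.table.equals(b.table)


class TestSeasonalHeading:
    def test_still_air_best_heading_is_the_orthodrome(self, still_air):
        cfg = _config()
        h, p = optimize_seasonal_heading(
            cfg, still_air, [DEP, DEP + np.timedelta64(1, "D")],
            heading_grid_deg=0.5, heading_span_deg=(-20.0, 20.0),
        )
        assert p == 1.0
        b = initial_bearing(START, GOAL)
        assert h == pytest.approx(b, abs=0.5)

    def test_alternating_crosswinds_compromise_on_the_orthodrome(self):
        # crosswind weak enough (0.1x self-speed, ~80 km drift) that the
        # compromise heading still arrives under both signs of the
        # 150 km arrival circle; stronger one-sided compensation fails
        # the opposite sign, so the symmetric heading wins
        b = initial_bearing(START, GOAL)
        left = _crosswind(1.2, b, offset_deg=90.0)
        right = _crosswind(1.2, b, offset_deg=-90.0)

        t_ref = DEP.astype("datetime64[s]").astype(float) - 6 * 3600.0

        class Alternating:
            """Crosswind whose sign flips between 48 h flight windows, so
            each flight experiences one sign throughout."""

            def velocity(self, lon, lat, time):
                block = ((np.asarray(time, dtype=float) - t_ref) // 172800.0).astype(int)
                u_l, v_l = left.velocity(lon, lat, time)
                u_r, v_r = right.velocity(lon, lat, time)
                odd = block % 2 == 1
                return np.where(odd, u_l, u_r), np.where(odd, v_l, v_r)

            def jacobian(self, lon, lat, time):
                return (0.0, 0.0, 0.0, 0.0)

            def covers(self, lon, lat, time):
                return True

        cfg = _config(arrival_radius_km=150.0)
        deps = [DEP + np.timedelta64(2 * k, "D") for k in range(4)]
        h, p = optimize_seasonal_heading(
            cfg, Alternating(), deps, heading_grid_deg=1.0,
            heading_span_deg=(-20.0, 20.0),
        )
        assert p == 1.0
        assert h == pytest.approx(b, abs=1.5)

    def test_single_date_reduces_to_the_event_solution(self, still_air):
        # a small arrival circle keeps the feasible heading band narrow,
        # so the seasonal pick coincides with the shooting solution
        cfg = _config(arrival_radius_km=5.0)
        h, p = optimize_seasonal_heading(
            cfg, still_air, [DEP], heading_grid_deg=0.2,
            heading_span_deg=(-10.0, 10.0),
        )
        res = run_event(cfg, still_air, DEP, strategies=("optimal", "vector"))
        assert p == 1.0
        assert h == pytest.approx(res["vector"].initial_heading, abs=0.6)
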