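"""Experiment designs and performance metrics.

Metrics, relative to the time-optimal benchmark:

* efficiency  epsilon = T_optimal / T_strategy  (travel speed relative to
  optimal orientation, for the same start, goal and conditions);
* flow support = (goal distance / duration - self-speed) / self-speed,
  the proportional gain in travel speed due to flow (D/T - 1 in scaled
  planar units);
* success rate p_A = fraction of runs (dates or departure locations)
  reaching the arrival circle.

Experiment designs: single migration events in time-varying wind with
all four strategies; departure-location sweeps within rotational flow;
and the seasonal single-heading optimization for vector orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import NoFeasibleHeadingError
from .flows import rotational_flow
from .geodesy import EarthModel, great_circle_distance, initial_bearing
from .solar import departure_after_civil_dusk
from .sphere import (
    GeoTrajectory,
    SphereConfig,
    _run_batch,
    integrate_sphere,
    solve_initial_heading_sphere,
)
from .strategies import (
    STRATEGIES,
    ShootingConfig,
    Trajectory,
    integrate_planar,
    solve_initial_heading,
)

# ---------------------------------------------------------------------------
# metrics


def efficiency(duration: float, optimal_duration: float) -> float:
    """epsilon = optimal duration / realized duration (NaN if either run
    failed to arrive)."""
    if duration is None or optimal_duration is None:
        return math.nan
    if not (np.isfinite(duration) and np.isfinite(optimal_duration)):
        return math.nan
    return optimal_duration / duration


def flow_support(goal_distance: float, duration: float, self_speed: float = 1.0) -> float:
    """Proportional gain in travel speed due to flow."""
    if not np.isfinite(duration):
        return math.nan
    return (goal_distance / duration - self_speed) / self_speed


@dataclass
class StrategyResult:
    """Outcome of one strategy on one event or departure location."""

    strategy: str
    arrived: bool
    duration: float
    efficiency: float
    flow_support: float
    closest_approach: float
    initial_heading: float = math.nan
    reason: str = ""


@dataclass(frozen=True)
class MigrationConfig:
    """Configuration of a spherical migration experiment.

    ``self_speed`` in m/s, ``arrival_radius_km`` in km, ``dt_s`` the
    integration step in seconds, ``interval_deg`` the heading-search
    interval width; ``level`` is the pressure level label (mb) used when
    subsetting wind files.
    """

    start: Tuple[float, float]
    goal: Tuple[float, float]
    arrival_radius_km: float
    self_speed: float
    level: Optional[float] = None
    dt_s: float = 120.0
    interval_deg: float = 1.0
    max_duration_s: Optional[float] = None
    dusk_offset_h: float = 1.0
    earth: EarthModel = EarthModel()

    def __post_init__(self):
        if self.arrival_radius_km <= 0 or self.self_speed <= 0 or self.dt_s <= 0:
            raise ValueError("arrival_radius_km, self_speed and dt_s must be > 0")

    def sphere_config(self, **overrides) -> SphereConfig:
        kw = dict(
            dt_s=self.dt_s,
            arrival_radius_km=self.arrival_radius_km,
            interval_width_deg=self.interval_deg,
            max_duration_s=self.max_duration_s,
            earth=self.earth,
        )
        kw.update(overrides)
        return SphereConfig(**kw)

    def departure_time(self, date) -> np.datetime64:
        """Departure timestamp for a calendar date: civil dusk at the
        departure location plus the configured offset."""
        return departure_after_civil_dusk(
            self.start[0], self.start[1], date, self.dusk_offset_h
        )


# ---------------------------------------------------------------------------
# single events on the sphere


def run_event(
    config: MigrationConfig,
    wind,
    departure,
    strategies: Sequence[str] = STRATEGIES,
    optimal_refine_s: float = 60.0,
    return_trajectories: bool = False,
) -> Dict[str, StrategyResult]:
    """Run all requested strategies for one departure.

    ``departure`` is an absolute timestamp.  Optimal and vector use the
    multi-start initial-heading search; the optimal search keeps refining
    until its duration changes by less than ``optimal_refine_s`` seconds.
    Efficiencies are relative to the optimal run (so optimal must be
    among the requested strategies for efficiencies to be defined).
    """
    cfg = config.sphere_config()
    D_km = great_circle_distance(config.start, config.goal, config.earth)
    trajs: Dict[str, GeoTrajectory] = {}
    psi0s: Dict[str, float] = {}

    for s in strategies:
        if s in ("optimal", "vector"):
            try:
                psi0, tr = solve_initial_heading_sphere(
                    wind, s, config.start, config.goal, departure,
                    config.self_speed, cfg,
                    require_arrival=False,
                    refine_duration_s=optimal_refine_s if s == "optimal" else None,
                )
                psi0s[s] = psi0
            except NoFeasibleHeadingError:
                tr = None
        else:
            tr = integrate_sphere(
                wind, s, config.start, config.goal, departure,
                config.self_speed, None, cfg,
            )
        trajs[s] = tr

    T_opt = math.nan
    if "optimal" in trajs and trajs["optimal"] is not None and trajs["optimal"].arrived:
        T_opt = trajs["optimal"].duration_s

    out: Dict[str, StrategyResult] = {}
    for s, tr in trajs.items():
        if tr is None:
            out[s] = StrategyResult(s, False, math.nan, math.nan, math.nan, math.nan)
            continue
        dur = tr.duration_s if tr.arrived else math.nan
        out[s] = StrategyResult(
            strategy=s,
            arrived=tr.arrived,
            duration=dur,
            efficiency=efficiency(dur, T_opt),
            flow_support=flow_support(D_km * 1000.0, dur, config.self_speed),
            closest_approach=tr.closest_approach_km,
            initial_heading=psi0s.get(s, tr.psi[0] if len(tr.psi) else math.nan),
            reason=tr.reason,
        )
    if return_trajectories:
        return out, trajs
    return out


def results_frame(results: Dict[str, StrategyResult], **extra) -> pd.DataFrame:
    """Tabulate per-strategy results (one row per strategy)."""
    rows = []
    for s, r in results.items():
        row = dict(
            strategy=s,
            arrived=r.arrived,
            duration_s=r.duration,
            efficiency=r.efficiency,
            flow_support=r.flow_support,
            closest_approach_km=r.closest_approach,
            psi0_deg=r.initial_heading,
            reason=r.reason,
        )
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planar benchmark experiments: feasibility thresholds and efficiency


def _threshold_config(config: Optional[ShootingConfig]) -> ShootingConfig:
    # max_time 20 (not the 5*D default): the vector duration diverges as
    # W -> 2 and a short cap would bias the recovered threshold low
    return config or ShootingConfig(dt=1e-3, max_time=20.0, interval_width_deg=1.0)


def shear_feasibility_threshold(
    strategy: str,
    precision: float = 0.01,
    config: Optional[ShootingConfig] = None,
) -> float:
    """Largest flow strength W at which the strategy still crosses the
    shear pattern from (0,0) to (0,1), by bisection to ``precision``.

    Full compensation fails beyond W = 1 (it becomes stationary where
    the lateral flow reaches the self-speed); vector orientation fails
    beyond W = 2 (the mean lateral flow W/2 can no longer be balanced).
    """
    from .flows import shear_flow

    config = _threshold_config(config)
    start, goal = (0.0, 0.0), (0.0, 1.0)

    def feasible(W: float) -> bool:
        flow = shear_flow(W)
        if strategy == "fullcomp":
            return integrate_planar(flow, "fullcomp", start, goal, None, config).arrived
        if strategy == "vector":
            try:
                _, tr = solve_initial_heading(flow, "vector", start, goal, config)
                return tr.arrived
            except NoFeasibleHeadingError:
                return False
        raise ValueError(f"no feasibility threshold for strategy {strategy!r}")

    lo, hi = (0.5, 1.5) if strategy == "fullcomp" else (1.5, 2.5)
    if not feasible(lo):
        raise RuntimeError(f"{strategy} unexpectedly infeasible at W={lo}")
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def rotational_vector_efficiency(
    W: float, config: Optional[ShootingConfig] = None
) -> float:
    """Vector-orientation efficiency T*/T^c for travel straight through
    rotational flow from (0,-1) to (0,1), both durations obtained by
    shooting."""
    from .flows import rotational_flow

    config = config or ShootingConfig(dt=1e-3)
    flow = rotational_flow(W)
    start, goal = (0.0, -1.0), (0.0, 1.0)
    _, tr_opt = solve_initial_heading(flow, "optimal", start, goal, config)
    _, tr_vec = solve_initial_heading(flow, "vector", start, goal, config)
    return tr_opt.duration / tr_vec.duration


# ---------------------------------------------------------------------------
# departure sweep in planar rotational flow


@dataclass
class SweepResult:
    """Aggregated departure-location sweep outcome."""

    table: pd.DataFrame
    success_rate: Dict[str, float]
    efficiency_quantiles: Dict[str, Tuple[float, float, float]]


def sweep_region(spacing: float = 0.01) -> np.ndarray:
    """Departure locations: the x >= 0 half of the lens where both the
    departure point and its goal one radius south lie inside the unit
    flow circle.  Returns an (N, 2) array."""
    xs = np.arange(0.0, 1.0 + spacing / 2, spacing)
    ys = np.arange(0.0, 1.0 + spacing / 2, spacing)
    X, Y = np.meshgrid(xs, ys)
    inside = (X**2 + Y**2 <= 1.0) & (X**2 + (Y - 1.0) ** 2 <= 1.0)
    return np.column_stack([X[inside], Y[inside]])


def departure_sweep_rotational(
    W: float,
    spacing: float = 0.01,
    strategies: Sequence[str] = STRATEGIES,
    config: Optional[ShootingConfig] = None,
    region: Optional[np.ndarray] = None,
) -> SweepResult:
    """Sweep departure locations within rotational flow.

    Each departure (x0, y0) targets the goal (x0, y0 - 1) one radius away
    on the opposite side of the pattern.  Success rates and efficiency
    quartiles (25/50/75%) are aggregated per strategy; efficiencies are
    relative to the optimal run from the same location.
    """
    flow = rotational_flow(W)
    config = config or ShootingConfig()
    pts = sweep_region(spacing) if region is None else np.asarray(region)
    rows: List[dict] = []
    for x0, y0 in pts:
        start, goal = (float(x0), float(y0)), (float(x0), float(y0) - 1.0)
        sub: Dict[str, Trajectory] = {}
        for s in strategies:
            if s in ("optimal", "vector"):
                try:
                    _, tr = solve_initial_heading(flow, s, start, goal, config)
                except NoFeasibleHeadingError:
                    tr = None
            else:
                tr = integrate_planar(flow, s, start, goal, None, config)
            sub[s] = tr
        T_opt = math.nan
        if sub.get("optimal") is not None and sub["optimal"].arrived:
            T_opt = sub["optimal"].duration
        for s, tr in sub.items():
            arrived = tr is not None and tr.arrived
            dur = tr.duration if arrived else math.nan
            rows.append(
                dict(
                    x0=x0, y0=y0, strategy=s, arrived=arrived,
                    duration=dur,
                    efficiency=efficiency(dur, T_opt),
                    flow_support=flow_support(1.0, dur),
                    closest_approach=(tr.closest_approach if tr is not None else math.nan),
                )
            )
    table = pd.DataFrame(rows)
    p_A = {
        s: float(table.loc[table.strategy == s, "arrived"].mean())
        for s in strategies
    }
    quantiles = {}
    for s in strategies:
        e = table.loc[(table.strategy == s) & table.arrived, "efficiency"].dropna()
        quantiles[s] = (
            tuple(np.quantile(e, [0.25, 0.5, 0.75])) if len(e) else (math.nan,) * 3
        )
    return SweepResult(table=table, success_rate=p_A, efficiency_quantiles=quantiles)


# ---------------------------------------------------------------------------
# seasonal single-heading optimization (vector orientation)


def optimize_seasonal_heading(
    config: MigrationConfig,
    wind,
    departures: Sequence,
    heading_grid_deg: float = 0.1,
    heading_span_deg: Tuple[float, float] = (-90.0, 90.0),
) -> Tuple[float, float]:
    """Choose the single constant heading maximizing the overall vector-
    orientation success rate over all departures.

    Candidate headings are offsets from the initial orthodrome bearing
    spanning ``heading_span_deg`` at ``heading_grid_deg`` spacing.  Ties
    are broken toward the orthodrome bearing.  Returns
    ``(best_heading_deg, p_A)``.
    """
    departures = list(departures)
    cfg = config.sphere_config()
    bearing = initial_bearing(config.start, config.goal)
    lo, hi = heading_span_deg
    headings = bearing + np.arange(lo, hi + heading_grid_deg / 2, heading_grid_deg)
    n_arrived = np.zeros(headings.size)
    for dep in departures:
        arr, _, _ = _run_batch(
            wind, headings, "vector", config.start, config.goal,
            np.datetime64(dep, "ns"), config.self_speed, cfg,
        )
        n_arrived += arr
    p = n_arrived / max(len(departures), 1)
    best_p = p.max()
    near = np.where(p >= best_p)[0]
    off = np.abs(headings[near] - bearing)
    best = near[np.argmin(off)]
    return float(headings[best] % 360.0), float(best_p)
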