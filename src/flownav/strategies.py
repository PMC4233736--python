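"""Planar orientation strategies and trajectory integration.

Implements the four orientation rules on the scaled plane:

* ``optimal`` — time-minimizing (Zermelo) control: the heading evolves by
  an ODE driven by the flow's spatial derivatives;
* ``vector`` — a single constant heading fixed at departure;
* ``goal`` — continually heading straight at the goal (map sense);
* ``fullcomp`` — continual heading adjustment that cancels lateral drift
  so the ground track holds the constant start-to-goal direction.

Headings ``psi`` are radians clockwise from the +y (goalward) axis, so
the self-propelled velocity is ``(sin psi, cos psi)`` at unit self-speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CompensationInfeasibleError, NoFeasibleHeadingError
from .flows import FlowFieldPlanar

STRATEGIES = ("optimal", "vector", "goal", "fullcomp")

_TWO_PI = 2.0 * math.pi


def wrap_angle(psi):
    """Wrap an angle (radians) to the interval (-pi, pi]."""
    psi = np.asarray(psi, float)
    out = -(np.mod(-psi + math.pi, _TWO_PI) - math.pi)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PlanarState:
    """Position, time and heading on the scaled plane."""

    x: float
    y: float
    t: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "psi", wrap_angle(self.psi))


@dataclass
class Trajectory:
    """A time-stamped planar track with arrival bookkeeping.

    ``duration`` is NaN when the traveller never arrived; ``reason``
    records why integration stopped ("arrived", "max_time", "infeasible").
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    psi: np.ndarray
    arrived: bool
    duration: float
    closest_approach: float
    reason: str = ""
    strategy: str = ""

    @property
    def states(self) -> Sequence[PlanarState]:
        return [
            PlanarState(float(x), float(y), float(t), float(p))
            for t, x, y, p in zip(self.t, self.x, self.y, self.psi)
        ]

    def to_frame(self, flow: Optional[FlowFieldPlanar] = None) -> pd.DataFrame:
        """Tabulate the track; with ``flow`` given, include the local flow
        velocity and ground speed per row."""
        df = pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "psi": self.psi})
        if flow is not None:
            u_w, v_w = flow.velocity_at(self.x, self.y, self.t)
            df["u_w"] = u_w
            df["v_w"] = v_w
            df["ground_speed"] = np.hypot(
                u_w + np.sin(self.psi), v_w + np.cos(self.psi)
            )
        return df

    def to_csv(self, path, flow: Optional[FlowFieldPlanar] = None, stride: int = 1):
        self.to_frame(flow).iloc[::stride].to_csv(path, index=False)


@dataclass(frozen=True)
class ShootingConfig:
    """Numerical settings for integration and initial-heading searches.

    ``interval_width_deg`` partitions heading space for the multi-start
    search; ``tolerance`` is the arrival distance; ``dt`` the integration
    step; ``max_time`` caps a run (default ``5 * D`` so that spiralling
    goal-orientation runs terminate).  ``method`` is "rk4" or "euler".
    """

    interval_width_deg: float = 1.0
    tolerance: float = 1e-3
    dt: float = 1e-3
    max_time: Optional[float] = None
    method: str = "rk4"
    scan_points_per_interval: int = 5
    refine_rounds: int = 7
    max_record: int = 4000

    def __post_init__(self):
        if self.interval_width_deg <= 0 or self.dt <= 0 or self.tolerance <= 0:
            raise ValueError("interval_width_deg, dt and tolerance must be > 0")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.method not in ("rk4", "euler"):
            raise ValueError("method must be 'rk4' or 'euler'")

    def resolved_max_time(self, start, goal) -> float:
        if self.max_time is not None:
            return self.max_time
        return 5.0 * math.hypot(goal[0] - start[0], goal[1] - start[1])


@dataclass(frozen=True)
class DurationPair:
    """Closed-form travel durations for the two analytic generic strategies.

    Either entry is None where the strategy is infeasible at that flow
    strength.
    """

    T_vector: Optional[float]
    T_fullcomp: Optional[float]


# ---------------------------------------------------------------------------
# elementary heading rules


def ground_velocity(psi, u_w, v_w):
    """Ground velocity = flow + unit self-propelled velocity at heading psi."""
    return u_w + np.sin(psi), v_w + np.cos(psi)


def zermelo_heading_rate(psi, du_dx, du_dy, dv_dx, dv_dy):
    """Time-minimizing heading rate on the plane.

    With headings clockwise from +y the Pontryagin condition gives

        dpsi/dt = sin^2(psi) du/dy - sin(psi)cos(psi) (du/dx - dv/dy)
                  - cos^2(psi) dv/dx.

    Zero in uniform flow; equal to ``-sense*W`` (constant) in solid-body
    rotational flow, so optimal headings there change linearly in time.
    """
    s, c = np.sin(psi), np.cos(psi)
    return s * s * du_dy - s * c * (du_dx - dv_dy) - c * c * dv_dx


def full_compensation_heading(track_direction, u_w, v_w, self_speed=1.0):
    """Heading that cancels the lateral flow about ``track_direction``.

    Returns the heading whose resulting ground velocity is parallel to the
    track direction.  Raises :class:`CompensationInfeasibleError` when the
    lateral flow component exceeds the self-speed.  When the lateral flow
    exactly equals the self-speed the heading is perpendicular to the
    track and the forward ground speed is zero (a stationary mover).
    """
    f_lat = u_w * math.cos(track_direction) - v_w * math.sin(track_direction)
    ratio = f_lat / self_speed
    if abs(ratio) > 1.0:
        raise CompensationInfeasibleError(
            f"lateral flow {f_lat:.4g} exceeds self-speed {self_speed:.4g}"
        )
    return wrap_angle(track_direction - math.asin(ratio))


def goal_heading(position, goal):
    """Heading from ``position`` straight toward ``goal`` (map sense)."""
    dx, dy = goal[0] - position[0], goal[1] - position[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("goal heading undefined at the goal point")
    return math.atan2(dx, dy)


# ---------------------------------------------------------------------------
# single-trajectory integration


def _heading_fn(flow, strategy, start, goal, initial_heading):
    """Return psi(x, y, t) for the state-determined strategies."""
    if strategy == "goal":

        def rule(x, y, t):
            if x == goal[0] and y == goal[1]:
                return 0.0
            return goal_heading((x, y), goal)

        return rule
    if strategy == "fullcomp":
        track = goal_heading(start, goal)

        def rule(x, y, t):
            u_w, v_w = flow.velocity_at(x, y, t)
            return full_compensation_heading(track, float(u_w), float(v_w))

        return rule
    raise ValueError(f"unknown state-determined strategy {strategy!r}")


def integrate_planar(
    flow: FlowFieldPlanar,
    strategy: str,
    start: Tuple[float, float],
    goal: Tuple[float, float],
    initial_heading: Optional[float] = None,
    config: Optional[ShootingConfig] = None,
) -> Trajectory:
    """Integrate one trajectory under the given strategy.

    ``initial_heading`` is required for "optimal" and "vector"; the other
    strategies determine their heading from the state.  Integration stops
    at arrival (distance to goal <= tolerance, with the duration linearly
    extrapolated to distance zero inside the final step), when full
    compensation becomes infeasible, or at ``max_time``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    config = config or ShootingConfig()
    if strategy in ("optimal", "vector"):
        if initial_heading is None:
            raise ValueError(f"{strategy} orientation requires an initial heading")
        psi = float(wrap_angle(initial_heading))
        rule = None
    else:
        rule = _heading_fn(flow, strategy, start, goal, None)
        psi = math.nan

    dt = config.dt
    max_time = config.resolved_max_time(start, goal)
    tol = config.tolerance
    n_steps = int(math.ceil(max_time / dt))
    stride = max(1, n_steps // config.max_record)
    xf, yf = float(goal[0]), float(goal[1])
    x, y, t = float(start[0]), float(start[1]), 0.0

    def deriv(x, y, psi, t):
        u_w, v_w = flow.velocity_at(x, y, t)
        u, v = ground_velocity(psi, float(u_w), float(v_w))
        if strategy == "optimal":
            j = flow.jacobian_at(x, y, t)
            dpsi = float(zermelo_heading_rate(psi, *map(float, j)))
        else:
            dpsi = 0.0
        return float(u), float(v), dpsi

    rec_t, rec_x, rec_y, rec_psi = [], [], [], []
    if rule is not None:
        try:
            psi = rule(x, y, t)
        except CompensationInfeasibleError:
            return Trajectory(
                t=np.asarray([0.0]), x=np.asarray([x]), y=np.asarray([y]),
                psi=np.asarray([math.nan]), arrived=False, duration=math.nan,
                closest_approach=math.hypot(x - xf, y - yf),
                reason="infeasible", strategy=strategy,
            )
    rec_t.append(t), rec_x.append(x), rec_y.append(y), rec_psi.append(psi)

    closest = math.hypot(x - xf, y - yf)
    t_closest = 0.0
    arrived = False
    duration = math.nan
    reason = "max_time"
    rk4 = config.method == "rk4"

    for k in range(n_steps):
        px, py = x, y
        try:
            if rule is not None:
                # heading updated once per step (stepwise heading updates);
                # position advanced with the heading frozen over the step
                psi = rule(x, y, t)
                if rk4:
                    u1, v1, _ = deriv(x, y, psi, t)
                    u2, v2, _ = deriv(x + 0.5 * dt * u1, y + 0.5 * dt * v1, psi, t + 0.5 * dt)
                    u3, v3, _ = deriv(x + 0.5 * dt * u2, y + 0.5 * dt * v2, psi, t + 0.5 * dt)
                    u4, v4, _ = deriv(x + dt * u3, y + dt * v3, psi, t + dt)
                    x += dt * (u1 + 2 * u2 + 2 * u3 + u4) / 6.0
                    y += dt * (v1 + 2 * v2 + 2 * v3 + v4) / 6.0
                else:
                    u1, v1, _ = deriv(x, y, psi, t)
                    x += dt * u1
                    y += dt * v1
                t += dt
            else:
                if rk4:
                    k1 = deriv(x, y, psi, t)
                    k2 = deriv(
                        x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1],
                        psi + 0.5 * dt * k1[2], t + 0.5 * dt,
                    )
                    k3 = deriv(
                        x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1],
                        psi + 0.5 * dt * k2[2], t + 0.5 * dt,
                    )
                    k4 = deriv(
                        x + dt * k3[0], y + dt * k3[1], psi + dt * k3[2], t + dt
                    )
                    x += dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
                    y += dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
                    psi += dt * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
                else:
                    u1, v1, dp = deriv(x, y, psi, t)
                    x += dt * u1
                    y += dt * v1
                    psi += dt * dp
                t += dt
        except CompensationInfeasibleError:
            reason = "infeasible"
            break

        tt, dmin = _segment_closest(
            np.float64(px - xf), np.float64(py - yf),
            np.float64(x - px), np.float64(y - py),
        )
        improving = float(dmin) < closest
        if improving:
            closest = float(dmin)
            t_closest = (t - dt) + dt * float(tt)
        if (k + 1) % stride == 0:
            rec_t.append(t), rec_x.append(x), rec_y.append(y), rec_psi.append(psi)
        if closest <= tol:
            arrived = True
            if not improving:
                # past the closest pass: the arrival time is fixed
                duration = t_closest
                reason = "arrived"
                break

    if arrived and math.isnan(duration):
        duration = t_closest
        reason = "arrived"
    if rec_t[-1] != t:
        rec_t.append(t), rec_x.append(x), rec_y.append(y), rec_psi.append(psi)

    return Trajectory(
        t=np.asarray(rec_t),
        x=np.asarray(rec_x),
        y=np.asarray(rec_y),
        psi=wrap_angle(np.asarray(rec_psi)),
        arrived=arrived,
        duration=duration,
        closest_approach=max(closest, 0.0),
        reason=reason,
        strategy=strategy,
    )


# ---------------------------------------------------------------------------
# batched integration over many candidate initial headings


def _batch(flow, psi0, start, goal, config: ShootingConfig, evolve: bool):
    """Integrate vector (``evolve=False``) or Zermelo (``evolve=True``)
    trajectories for an array of initial headings at once; returns
    ``(arrived, duration, closest_approach)`` arrays."""
    psi0 = np.atleast_1d(np.asarray(psi0, float))
    n = psi0.size
    x = np.full(n, float(start[0]))
    y = np.full(n, float(start[1]))
    psi = psi0.copy()
    xf, yf = float(goal[0]), float(goal[1])
    dt = config.dt
    tol = config.tolerance
    max_time = config.resolved_max_time(start, goal)
    n_steps = int(math.ceil(max_time / dt))
    rk4 = config.method == "rk4"

    arrived = np.zeros(n, bool)
    done = np.zeros(n, bool)
    duration = np.full(n, np.nan)
    closest = np.hypot(x - xf, y - yf)
    t_closest = np.zeros(n)

    def deriv(x, y, psi, t):
        u_w, v_w = flow.velocity_at(x, y, t)
        u = u_w + np.sin(psi)
        v = v_w + np.cos(psi)
        if evolve:
            dpsi = zermelo_heading_rate(psi, *flow.jacobian_at(x, y, t))
        else:
            dpsi = 0.0
        return u, v, dpsi

    t = 0.0
    for k in range(n_steps):
        px, py = x, y
        if rk4:
            k1 = deriv(x, y, psi, t)
            k2 = deriv(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1],
                       psi + 0.5 * dt * k1[2], t + 0.5 * dt)
            k3 = deriv(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1],
                       psi + 0.5 * dt * k2[2], t + 0.5 * dt)
            k4 = deriv(x + dt * k3[0], y + dt * k3[1], psi + dt * k3[2], t + dt)
            x = x + dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
            y = y + dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
            if evolve:
                psi = psi + dt * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        else:
            u, v, dpsi = deriv(x, y, psi, t)
            x = x + dt * u
            y = y + dt * v
            if evolve:
                psi = psi + dt * dpsi
        t += dt
        # closest approach along the straight step segment, so the
        # continuous minimum is not missed between samples
        tt, dmin = _segment_closest(px - xf, py - yf, x - px, y - py)
        improving = (~done) & (dmin < closest)
        closest[improving] = dmin[improving]
        t_closest[improving] = (t - dt) + dt * tt[improving]
        arrived = closest <= tol
        # freeze the arrival time once an arrived trajectory recedes from
        # its closest pass
        newly_done = arrived & ~improving & ~done
        if newly_done.any():
            duration[newly_done] = t_closest[newly_done]
            done[newly_done] = True
        if done.all():
            break
    pending = arrived & ~done
    duration[pending] = t_closest[pending]
    return arrived, duration, closest


def _segment_closest(rx, ry, sx, sy):
    """Minimum distance to the origin along the segment r + tt*s for
    tt in [0, 1]; returns (tt_at_min, min_distance)."""
    seg2 = sx * sx + sy * sy
    tt = np.clip(-(rx * sx + ry * sy) / np.where(seg2 > 0, seg2, 1.0), 0.0, 1.0)
    return tt, np.hypot(rx + tt * sx, ry + tt * sy)


def _score(arrived, duration, closest, max_time):
    """Within-interval search score: the closest approach to the goal.

    Refinement always drives the closest approach toward zero (the
    exact-arrival heading of that interval); durations are compared only
    *across* intervals afterwards.  Minimizing arrival time inside the
    tolerance band instead would bias durations low by up to the arrival
    tolerance."""
    return closest


def solve_initial_heading(
    flow: FlowFieldPlanar,
    strategy: str,
    start: Tuple[float, float],
    goal: Tuple[float, float],
    config: Optional[ShootingConfig] = None,
    require_arrival: bool = True,
) -> Tuple[float, Trajectory]:
    """Multi-start shooting for the departure heading.

    Heading space (-pi, pi] is partitioned into intervals of
    ``interval_width_deg`` anchored at psi = 0 (goalward).  Each interval
    is scanned; promising intervals are refined with a deterministic
    nested grid that minimizes the closest approach to the goal until the
    heading bracket collapses; the winner is then chosen *across*
    intervals among the arrival-feasible refined headings by smallest
    duration, with ties broken by smallest ``|psi0|``.

    Raises :class:`NoFeasibleHeadingError` when no heading reaches the
    goal within tolerance (unless ``require_arrival`` is False, in which
    case the best closest-approach solution is returned).
    """
    if strategy not in ("optimal", "vector"):
        raise ValueError("initial-heading search applies to optimal/vector only")
    config = config or ShootingConfig()
    evolve = strategy == "optimal"
    max_time = config.resolved_max_time(start, goal)

    w = math.radians(config.interval_width_deg)
    n_int = max(1, int(round(_TWO_PI / w)))
    w = _TWO_PI / n_int
    edges = -math.pi + w * np.arange(n_int + 1)
    # anchor the partition at psi = 0
    edges = edges - (edges[np.argmin(np.abs(edges))])

    m = max(2, config.scan_points_per_interval)
    offs = np.linspace(0.0, 1.0, m, endpoint=False) + 0.5 / m
    scan = (edges[:-1, None] + w * offs[None, :]).ravel()
    arr, dur, clo = _batch(flow, scan, start, goal, config, evolve)
    sc = _score(arr, dur, clo, max_time).reshape(n_int, m)
    int_best = sc.min(axis=1)

    feasible_ints = np.where(arr.reshape(n_int, m).any(axis=1))[0]
    order = np.argsort(int_best)
    cand = list(order[: max(3, feasible_ints.size)])
    for i in feasible_ints:
        if i not in cand:
            cand.append(int(i))
    cand = np.asarray(cand[:12])

    lo = edges[cand].astype(float)
    hi = edges[cand + 1].astype(float)
    for _ in range(config.refine_rounds):
        pts = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, 9)[None, :]
        arr, dur, clo = _batch(flow, pts.ravel(), start, goal, config, evolve)
        sc = _score(arr, dur, clo, max_time).reshape(len(cand), 9)
        i_best = sc.argmin(axis=1)
        span = hi - lo
        ctr = pts[np.arange(len(cand)), i_best]
        lo = np.maximum(lo, ctr - span / 8.0)
        hi = np.minimum(hi, ctr + span / 8.0)

    # final evaluation at the refined headings (one per candidate interval)
    finals = 0.5 * (lo + hi)
    arr, dur, clo = _batch(flow, finals, start, goal, config, evolve)
    if arr.any():
        durs = np.where(arr, dur, np.inf)
        near = durs <= durs.min() + 1e-9
        idx = np.where(near)[0]
        best = int(idx[np.argmin(np.abs(finals[idx]))])
        psi0 = float(wrap_angle(finals[best]))
        traj = integrate_planar(flow, strategy, start, goal, psi0, config)
        if traj.arrived:
            return psi0, traj
    if require_arrival:
        raise NoFeasibleHeadingError(
            f"no {strategy} heading reaches the goal within "
            f"{config.tolerance:g} (best approach {clo.min():.4g})"
        )
    best = int(np.argmin(clo))
    psi0 = float(wrap_angle(finals[best]))
    return psi0, integrate_planar(flow, strategy, start, goal, psi0, config)
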