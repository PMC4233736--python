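"""Analytic trajectories and travel durations in the steady patterns.

For the standard crossings — shear flow from (0, 0) to (0, 1) and
rotational flow from (0, -1) to (0, 1) — the vector-orientation and
time-optimal trajectories admit closed forms; the generic durations
T^c (vector) and T^F (full compensation) are elementary functions of the
flow strength W.

Derivations (all in self-speed units, headings clockwise from +y):

Shear flow (u_w, v_w) = (W y, 0):
  * vector: y = t cos(psi0), x = (W/2) t^2 cos(psi0) + t sin(psi0);
    arrival forces sin(psi0) = -W/2 (the mean lateral flow is W/2), so
    T^c = 1 / sqrt(1 - W^2/4), feasible for W < 2.
  * full compensation: sin(psi) = -W y, forward speed sqrt(1 - W^2 y^2),
    so T^F = asin(W) / W, feasible for W <= 1 (stationary where W y = 1).
  * optimal: the Zermelo rate gives d(cot psi)/dt = -W, the classic
    linear-shear solution; x, y, t are elementary functions of psi and
    the initial heading solves a scalar boundary condition x(psi_f) = 0.

Rotational flow (u_w, v_w) = W (-y, x):
  * vector: in complex position z = x + i y the track is a circular arc
    about z* = -e^{-i psi0} / W; passing through both endpoints forces
    psi0 = 0 (full drift) and T^c = 2 atan(W) / W.
  * full compensation: T^F = 2 asin(W) / W, feasible for W <= 1.
  * optimal: dpsi/dt = -W, z(t) = e^{iWt} (z0 + i t e^{-i psi0}); the
    arrival condition reduces to T = 2 cos(W T / 2) with psi0 = W T / 2.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import OutOfRangeError
from .strategies import DurationPair, Trajectory, wrap_angle


def shear_durations_closed_form(W: float) -> DurationPair:
    """Closed-form shear-crossing durations ``(T_vector, T_fullcomp)``.

    Entries are None beyond the feasibility limits (W >= 2 for vector
    orientation, W > 1 for full compensation).
    """
    if W < 0:
        raise OutOfRangeError("W must be >= 0")
    T_vec = 1.0 / math.sqrt(1.0 - W * W / 4.0) if W < 2.0 else None
    if W == 0.0:
        T_fc = 1.0
    elif W <= 1.0:
        T_fc = math.asin(W) / W
    else:
        T_fc = None
    return DurationPair(T_vector=T_vec, T_fullcomp=T_fc)


def rotational_durations_closed_form(W: float) -> DurationPair:
    """Closed-form durations for travel straight through rotational flow."""
    if W < 0:
        raise OutOfRangeError("W must be >= 0")
    T_vec = 2.0 if W == 0.0 else 2.0 * math.atan(W) / W
    if W == 0.0:
        T_fc = 2.0
    elif W <= 1.0:
        T_fc = 2.0 * math.asin(W) / W
    else:
        T_fc = None
    return DurationPair(T_vector=T_vec, T_fullcomp=T_fc)


def rotational_optimal_duration(W: float) -> Tuple[float, float]:
    """Optimal duration T* and initial heading psi0 through rotational flow.

    T* is the unique root of T = 2 cos(W T / 2) on (0, min(2, pi/W)),
    and psi0 = W T* / 2 (headings then decrease linearly at rate W,
    turning with the counter-clockwise flow).
    """
    if W < 0:
        raise OutOfRangeError("W must be >= 0")
    if W == 0.0:
        return 2.0, 0.0
    hi = min(2.0, math.pi / W - 1e-12)
    T = brentq(lambda T: T - 2.0 * math.cos(W * T / 2.0), 1e-12, hi, xtol=1e-14)
    return float(T), W * T / 2.0


def _shear_optimal_xyt(psi, psi0, W):
    """Closed-form (x, y, t) along the shear-flow optimal path, as a
    function of the current heading psi in (-pi, 0)."""
    s0 = math.sin(psi0)
    s, c = np.sin(psi), np.cos(psi)
    t = (math.cos(psi0) / s0 - c / s) / W
    y = (1.0 / s0 - 1.0 / s) / W

    def G(p):
        sp, cp = np.sin(p), np.cos(p)
        return (-cp / sp / s0
                + cp / (2.0 * sp * sp)
                + 0.5 * np.log(np.abs(np.tan(p / 2.0))))

    x = (G(psi) - G(psi0)) / W
    return x, y, t


def shear_optimal_solution(W: float):
    """Initial heading, final heading and duration of the time-optimal
    shear crossing, from the closed form plus one scalar root-find."""
    if W <= 0:
        if W == 0:
            return 0.0, 0.0, 1.0
        raise OutOfRangeError("W must be >= 0")

    def psi_f(psi0):
        return math.asin(1.0 / (1.0 / math.sin(psi0) - W))

    def x_final(psi0):
        pf = psi_f(psi0)
        x, _, _ = _shear_optimal_xyt(np.asarray(pf), psi0, W)
        return float(x)

    # bracket roots of x(psi_f) = 0 over upstream initial headings and
    # keep the fastest crossing
    grid = -np.linspace(1e-6, math.pi - 1e-3, 400)[::-1]
    vals = np.array([x_final(p) for p in grid])
    idx = np.where(np.diff(np.sign(vals)) != 0)[0]
    if idx.size == 0:
        raise OutOfRangeError(f"no optimal shear heading found for W={W}")
    best = None
    for i in idx:
        psi0 = brentq(x_final, grid[i], grid[i + 1], xtol=1e-13)
        pf = psi_f(psi0)
        _, _, T = _shear_optimal_xyt(np.asarray(pf), psi0, W)
        if best is None or T < best[2]:
            best = (float(psi0), float(pf), float(T))
    return best


def analytic_trajectories_closed_form(
    pattern: str,
    strategy: str,
    W: float,
    n_samples: int = 2001,
) -> Trajectory:
    """Closed-form trajectory for the supported (pattern, strategy) pairs.

    Patterns use their standard configurations: shear from (0, 0) to
    (0, 1), rotational from (0, -1) to (0, 1).  Supported strategies are
    "vector" and "optimal"; goal orientation and full compensation have
    no closed-form trajectories and raise :class:`OutOfRangeError`.
    """
    if strategy not in ("vector", "optimal"):
        raise OutOfRangeError(
            f"no closed-form trajectory for strategy {strategy!r}"
        )
    if pattern not in ("shear", "rotational"):
        raise OutOfRangeError(f"unknown pattern {pattern!r}")
    if W < 0:
        raise OutOfRangeError("W must be >= 0")

    if pattern == "shear":
        if strategy == "vector":
            pair = shear_durations_closed_form(W)
            if pair.T_vector is None:
                raise OutOfRangeError(f"vector orientation infeasible at W={W}")
            T = pair.T_vector
            psi0 = -math.asin(W / 2.0)
            t = np.linspace(0.0, T, n_samples)
            c, s = math.cos(psi0), math.sin(psi0)
            x = 0.5 * W * t * t * c + t * s
            y = t * c
            psi = np.full_like(t, psi0)
        else:
            if W == 0.0:
                t = np.linspace(0.0, 1.0, n_samples)
                x, y, psi = np.zeros_like(t), t.copy(), np.zeros_like(t)
            else:
                psi0, psif, T = shear_optimal_solution(W)
                t = np.linspace(0.0, T, n_samples)
                cot = 1.0 / math.tan(psi0) - W * t
                psi = np.arctan2(1.0, cot) - math.pi
                psi[0] = psi0
                x, y, _ = _shear_optimal_xyt(psi, psi0, W)
                x[0], y[0] = 0.0, 0.0
    else:
        z0 = -1j
        if strategy == "vector":
            T = rotational_durations_closed_form(W).T_vector
            t = np.linspace(0.0, T, n_samples)
            psi0 = 0.0
            if W == 0.0:
                z = z0 + 1j * t
            else:
                zc = -1.0 / W
                z = zc + (z0 - zc) * np.exp(1j * W * t)
            psi = np.full_like(t, psi0)
            x, y = z.real, z.imag
        else:
            T, psi0 = rotational_optimal_duration(W)
            t = np.linspace(0.0, T, n_samples)
            z = np.exp(1j * W * t) * (z0 + 1j * t * np.exp(-1j * psi0))
            psi = psi0 - W * t
            x, y = z.real, z.imag

    return Trajectory(
        t=t,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        psi=wrap_angle(np.asarray(psi, float)),
        arrived=True,
        duration=float(t[-1]),
        closest_approach=0.0,
        reason="arrived",
        strategy=strategy,
    )
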