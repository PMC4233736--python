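"""Steady planar flow patterns with exact velocities and spatial derivatives.

All planar quantities are dimensionless: velocities are expressed in units
of the traveller's self-speed ``V_a``, lengths in units of the pattern
scale ``L`` (the initial goal distance for shear flow, the pattern radius
for rotational flow) and time in units of ``L / V_a``.  In this scaling
the still-air travel duration equals the initial goal distance ``D``.

Coordinate convention: the ``y`` axis points from the departure location
toward the goal; headings are measured clockwise from ``+y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np

ArrayLike = "np.typing.ArrayLike"

#: velocity callable signature: (x, y, t) -> (u_w, v_w)
VelocityFn = Callable[[np.ndarray, np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]
#: jacobian callable signature: (x, y, t) -> (du/dx, du/dy, dv/dx, dv/dy)
JacobianFn = Callable[
    [np.ndarray, np.ndarray, np.ndarray],
    Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
]


@dataclass(frozen=True)
class FlowFieldPlanar:
    """A horizontal flow field on the scaled plane.

    Wraps a velocity function and the analytic Jacobian of that same
    velocity, which the time-optimal (Zermelo) heading equation needs.
    Both callables accept scalars or broadcastable arrays.
    """

    _velocity: VelocityFn
    _jacobian: JacobianFn
    name: str = "flow"
    params: Dict[str, float] = field(default_factory=dict)

    def velocity_at(self, x, y, t=0.0) -> Tuple[np.ndarray, np.ndarray]:
        """Flow velocity ``(u_w, v_w)`` in self-speed units at ``(x, y, t)``."""
        x, y, t = np.asarray(x, float), np.asarray(y, float), np.asarray(t, float)
        return self._velocity(x, y, t)

    def jacobian_at(self, x, y, t=0.0):
        """The four spatial partials ``(du/dx, du/dy, dv/dx, dv/dy)``."""
        x, y, t = np.asarray(x, float), np.asarray(y, float), np.asarray(t, float)
        return self._jacobian(x, y, t)


@dataclass(frozen=True)
class ShearFlowParams:
    """Shear flow strength.

    ``W`` is the maximum flow speed relative to self-speed, reached on the
    goal line ``y = 1``.
    """

    W: float

    def __post_init__(self):
        if self.W < 0:
            raise ValueError(f"flow strength W must be >= 0, got {self.W}")


@dataclass(frozen=True)
class RotationalFlowParams:
    """Rotational (solid-body) flow strength.

    ``W`` is the flow speed at unit radius, in self-speed units.  ``sense``
    is +1 for counter-clockwise rotation (the default, matching cyclonic
    flow in the northern hemisphere) and -1 for clockwise.
    """

    W: float
    sense: int = 1

    def __post_init__(self):
        if self.W < 0:
            raise ValueError(f"flow strength W must be >= 0, got {self.W}")
        if self.sense not in (-1, 1):
            raise ValueError("sense must be +1 (counter-clockwise) or -1")


def uniform_flow(u: float, v: float) -> FlowFieldPlanar:
    """Spatially uniform flow ``(u, v)`` in self-speed units."""

    def vel(x, y, t):
        shape = np.broadcast(x, y, t).shape
        return np.full(shape, float(u)), np.full(shape, float(v))

    def jac(x, y, t):
        z = np.zeros(np.broadcast(x, y, t).shape)
        return z, z.copy(), z.copy(), z.copy()

    return FlowFieldPlanar(vel, jac, name="uniform", params={"u": u, "v": v})


def shear_flow(params: ShearFlowParams | float) -> FlowFieldPlanar:
    """Lateral shear flow ``(u_w, v_w) = (W*y, 0)``.

    Flow is purely lateral (along +x), zero on the departure line ``y = 0``
    and increasing linearly to ``W`` on the goal line ``y = 1``; the mean
    lateral flow over the crossing is ``W/2``.
    """
    if not isinstance(params, ShearFlowParams):
        params = ShearFlowParams(float(params))
    W = params.W

    def vel(x, y, t):
        shape = np.broadcast(x, y, t).shape
        return np.broadcast_to(W * y, shape).copy(), np.zeros(shape)

    def jac(x, y, t):
        z = np.zeros(np.broadcast(x, y, t).shape)
        return z, np.full_like(z, W), z.copy(), z.copy()

    return FlowFieldPlanar(vel, jac, name="shear", params={"W": W})


def rotational_flow(params: RotationalFlowParams | float) -> FlowFieldPlanar:
    """Solid-body rotational flow about the origin.

    Purely tangential with speed ``W*r`` at radius ``r`` (the linear law is
    extended beyond ``r = 1``, which the analytic trajectory solutions
    require).  Counter-clockwise for ``sense=+1``:
    ``(u_w, v_w) = W * (-y, x)``.  The field is divergence-free.
    """
    if not isinstance(params, RotationalFlowParams):
        params = RotationalFlowParams(float(params))
    W, s = params.W, params.sense

    def vel(x, y, t):
        shape = np.broadcast(x, y, t).shape
        u = np.broadcast_to(-s * W * y, shape).copy()
        v = np.broadcast_to(s * W * x, shape).copy()
        return u, v

    def jac(x, y, t):
        z = np.zeros(np.broadcast(x, y, t).shape)
        return z, np.full_like(z, -s * W), np.full_like(z, s * W), z.copy()

    return FlowFieldPlanar(
        vel, jac, name="rotational", params={"W": W, "sense": s}
    )
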