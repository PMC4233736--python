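# Methods

## Model

A traveller moves at constant self-speed `V_a` through a horizontal flow
field; its ground velocity is the vector sum of self-propulsion and
flow.  Vertical structure, variable self-speed, energetics and the
Coriolis effect are outside the model (Coriolis is assumed negligible or
compensated by the animal).  On the plane all quantities are
non-dimensional: velocities in units of `V_a`, lengths in units of the
pattern scale `L` (the initial goal distance for shear flow, the vortex
radius for rotational flow), time in units of `L/V_a`.  The still-air
travel time therefore equals the initial goal distance `D` (1 for the
shear crossing, 2 for the diametric rotational crossing).

Headings `ψ` are measured clockwise from the goalward `+y` axis
(planar) or from geographic north (sphere), so self-propulsion is
`(sin ψ, cos ψ)`.

### Time-optimal orientation

Minimizing arrival time with the heading as control gives, via the
Pontryagin maximum principle, an ODE for the heading driven by the
flow's spatial derivatives:

    dψ/dt = sin²ψ u_y − sinψ cosψ (u_x − v_y) − cos²ψ v_x ,

with `u_x = ∂u_w/∂x` etc.  The whole optimal-control problem collapses
to choosing the initial heading.  Checks wired into the test suite:
the rate vanishes identically in uniform flow (where full compensation
is optimal); in solid-body rotation `(u_w, v_w) = W(−y, x)` it equals
`−W` exactly, so optimal headings change linearly in time, turning with
the flow; in linear shear `u_w = W y` it gives `d(cot ψ)/dt = −W`, the
classic linear-shear solution with compensation *decreasing* on
approach to the goal.

On the sphere, with winds in m/s and positions in longitude/latitude,
the same expression holds in local east/north per-metre derivatives plus
a curvature term

    (tan θ / R_e) · sinψ · (V_a + U_w sinψ + V_w cosψ),

derived from the Hamiltonian in (lon, lat) coordinates.  With zero wind
it reduces to the geodesic bearing drift (`dψ/dt = dφ/dt · sinθ`), and
the test suite verifies Clairaut's relation `sinψ cosθ = const` along
still-air optimal paths and tangent-plane agreement with the planar rate
for a vortex much smaller than the Earth.

### Closed forms for the steady patterns

Shear flow `(u_w, v_w) = (W y, 0)`, crossing (0,0)→(0,1):

* vector: `ψ0 = −asin(W/2)`, `T^c = 1/√(1 − W²/4)` (feasible W < 2 —
  the constant heading must balance the mean drift W/2);
* full compensation: `sinψ = −W y`, `T^F = asin(W)/W` (feasible W ≤ 1 —
  stationary where the lateral flow reaches the self-speed);
* optimal: `cot ψ` linear in time; positions are elementary functions of
  `ψ` and the initial heading solves the scalar boundary condition
  `x(ψ_f) = 0` (one Brent root-find).

Rotational flow `W(−y, x)`, crossing (0,−1)→(0,1):

* vector: circular-arc tracks about `z* = −e^{−iψ0}/W` (complex
  notation); passing through both endpoints forces `ψ0 = 0` — vector
  orientation coincides with full drift here — and `T^c = 2 atan(W)/W`;
* full compensation: `T^F = 2 asin(W)/W` (W ≤ 1);
* optimal: `z(t) = e^{iWt}(z0 + i t e^{−iψ0})`; the arrival condition
  reduces to `T = 2 cos(WT/2)` with `ψ0 = W T*/2` (scalar root).

These closed forms and the independent numerical integrators are kept as
dual routes and cross-checked to 1e-3 (sup-norm on trajectories,
relative on durations) in the tests.

## Numerics

* **Integration**: explicit RK4 at `dt = 1e-3` dimensionless (planar) by
  default; Euler at arbitrary `dt` is available.  The vector-orientation
  dynamics in shear flow are polynomial in time, so RK4 integrates them
  exactly; for the stiffest case used (rotational W = 10) the angular
  step `W·dt` stays ≤ 0.02.  Spherical integration uses RK4 in
  (lon, lat, ψ) degrees at `dt = 120 s` by default (thrush-scale events;
  60 s is appropriate for multi-day flights).
* **Headings of the state-determined strategies** (goal orientation,
  full compensation) update once per time step and stay frozen across
  the RK stages.  Re-evaluating them inside stages creates a spurious
  stall point at the goal (opposing stage headings average to zero
  velocity).
* **Arrival**: the goal-relative distance is minimized along each
  straight step segment, not only at step endpoints, so passes between
  samples are not missed.  Planar duration is the time of the closest
  pass (tolerance 1e-3, matching the exact-arrival closed forms to
  ~1e-6); spherical duration is the first crossing of the arrival
  circle (the "within 100 km" arrival definition), interpolated within
  the step.  Failed runs report the closest approach.
* **Initial-heading search**: heading space is partitioned into
  intervals (default 1°, anchored at the goalward heading); every
  interval is scanned with a vectorized batch integration, promising
  intervals are refined by a deterministic nested 9-point grid that
  minimizes the *closest approach* (converging on each interval's
  exact-arrival heading), and the arrival-feasible refined heading with
  the smallest duration wins; ties break toward the smallest heading
  offset.  Minimizing duration *inside* the arrival tolerance band
  instead would bias durations low by up to the tolerance — this is why
  the within-interval objective is distance, not time.  For the optimal
  benchmark on the sphere the refinement keeps going until the winning
  duration changes by less than 60 s.
* **max_time**: runs are capped at 5× the still-air duration by default
  (goal orientation can spiral indefinitely in strong rotational flow).
  The feasibility-threshold experiments use a cap of 20 instead: the
  vector duration `1/√(1−W²/4)` diverges as W→2, and a cap of 5 would
  misplace the recovered threshold at 1.96 rather than 2.00.
* **Feasibility thresholds** are found by bisection to ±0.01 on W, each
  candidate classified by actually running the strategy.
* **Full compensation** raises an infeasibility error the moment the
  lateral flow component exceeds the self-speed; the run is then a
  failure (mirroring terminating simulations when wind speed exceeds
  airspeed).

## Winds

Gridded winds hold eastward/northward components on a (time, lat, lon)
grid in m/s, read from/written to classic NetCDF with reanalysis-style
variable names (`uwnd`/`vwnd`, configurable), with pressure-level
selection, bbox/timespan subsetting and longitude normalization to
(−180, 180].  Interpolation is bilinear in space and linear in time; the
spatial derivatives used by the optimal heading equation are the
analytic derivatives *of that interpolant* (piecewise constant per cell,
time-blended), so the velocities that move the animal and the gradients
that steer it are internally consistent.  No extrapolation: queries
outside the grid fail loudly, and batch trajectories leaving the domain
are frozen and classed as failures.

The synthetic wind generator composes analytic primitives — uniform
flow, Gaussian zonal jets, translating vortices with a smooth
`(r/rc)·exp((1−(r/rc)²)/2)` tangential profile — each with exact values
and derivatives anywhere, and can grid them to emulate a reanalysis
file.  What the synthetic fields deliberately emulate: smooth,
divergence-structured flows with realistic magnitudes (peak vortex winds
up to ~1.5× a passerine's 12 m/s airspeed, jets of 15–20 m/s).  What
they do not emulate: mesoscale turbulence, fronts, vertical shear, or
the spatio-temporal error structure of real reanalysis products —
passing tests therefore demonstrates correctness of the machinery and
the qualitative strategy ranking, not forecasts for any real migration
system.

## Experiment designs

* **Events**: departure one hour after civil dusk (NOAA solar-position
  series, evening crossing of solar elevation −6°); all four strategies
  run from the same departure; efficiency is optimal duration over
  realized duration; flow support is `(distance/duration − V_a)/V_a`.
* **Departure sweep** (rotational flow): departures on a regular grid in
  the x ≥ 0 half of the lens where both the departure point and its goal
  one radius south lie inside the unit flow circle; default spacing
  0.01 gives ≈ 6.1 k locations (region and spacing are parameters; the
  sweep region is one of the genuinely open design choices — the
  alternative readings of "one quadrant" change N but not the strategy
  ranking, which is what the sweep measures).
* **Seasonal heading**: brute force over a heading grid (default 0.1°
  across the half-circle facing the goal), maximizing the fraction of
  departures that arrive; ties break toward the orthodrome bearing.

## Defaults with units

| parameter | default | note |
|---|---|---|
| Earth radius | 6378.1 km | equatorial; reproduces the 794 km and 5909 km case-study goal distances, which a 6371 km mean radius does not |
| planar dt | 1e-3 (scaled) | RK4 |
| planar arrival tolerance | 1e-3 (scaled) | |
| sphere dt | 120 s | 60 s for multi-day flights |
| arrival radius | 100 km | case-study scale; 250 km for the long-haul design |
| heading interval | 1° | 0.05° appropriate for ~6000 km flights |
| max_time | 5 × still-air duration | 20 for threshold bisections |
| self-speed | 12 m/s (short events) | 20 m/s long-haul |

## Problem sizes used by tests and the acceptance script

Tests run the planar work at `dt` between 1e-3 and 5e-3 with 2–5°
search intervals, sweeps at 0.4 spacing, and sphere events at
`dt = 180 s` with 5° intervals and a 20 km arrival radius — sizes chosen
so the full suite completes in minutes while staying within the stated
tolerances (RK4 keeps integration error far below the 1e-3 acceptance
bands at these steps).  The acceptance script bisects thresholds to
±0.005 and evaluates the six-point rotational efficiency grid at
`dt = 2e-3`.

## Known limitations

* Optimal orientation assumes perfect flow knowledge; it is a benchmark,
  not a behavioural model.
* Full compensation targets the orthodrome; rhumb-line-target
  compensation is not implemented.
* The multi-start search guarantees only interval-resolution coverage:
  extremals separated by less than the interval width can be missed
  (narrow intervals, 0.05°, were needed for a minority of long-haul
  flights in the motivating use case).
* The spherical integrator refuses pole crossings and does not model
  ellipsoidal geodesy.
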