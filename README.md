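# flownav

Time-optimal (Zermelo) orientation benchmarks for animal movement in
horizontal flows.

Migrating birds, fish and turtles move through air and water that move
with them: winds and currents can dwarf an animal's own speed, and how
it orients — whether it cancels drift, holds an inherited compass
heading, or continually re-aims at the goal — decides whether it arrives
at all and how long the journey takes. `flownav` simulates a traveller
moving at constant self-speed `V_a` through horizontal flow and compares
three generic orientation strategies against the absolute benchmark of
**time-minimizing (optimal) orientation** from control theory:

* **full compensation** — continually offset the heading so the ground
  track holds the great-circle (goalward) direction;
* **vector orientation** — a single constant heading fixed at departure;
* **goal orientation** — always head straight at the goal (map sense);
* **optimal orientation** — perfect flow knowledge; the heading `ψ`
  (clockwise from the goalward axis / north) evolves by Zermelo's
  equation.  On the plane, with flow `(u_w, v_w)` scaled to self-speed,

      dψ/dt = sin²ψ ∂u_w/∂y − sinψ cosψ (∂u_w/∂x − ∂v_w/∂y) − cos²ψ ∂v_w/∂x

  and on the sphere the same expression in local east/north coordinates
  gains a curvature term `(tan θ / R_e) sinψ (V_a + U_w sinψ + V_w cosψ)`
  so that still-air solutions are great circles.

Because only the *initial* heading is free, arrival becomes a shooting
problem: headings are searched in small intervals, each interval refined
to its exact-arrival heading, and the fastest arrival wins.

The package provides:

* analytic steady flow patterns (uniform, lateral shear, solid-body
  rotation) with exact velocities and derivatives, closed-form
  trajectories and durations, and planar trajectory integration
  (`flownav.flows`, `flownav.strategies`, `flownav.closed_forms`);
* spherical kinematics with great-circle geodesy, time-varying gridded
  winds (NetCDF, reanalysis-style layout) with internally consistent
  bilinear interpolation and derivatives, plus synthetic wind fields
  (uniform, zonal jets, translating vortices) with exact analytic values
  for testing (`flownav.sphere`, `flownav.wind`, `flownav.geodesy`);
* experiment designs and metrics: efficiency ε (speed relative to
  optimal), flow support, success rate `p_A`, departure-location sweeps,
  civil-dusk departure scheduling and seasonal single-heading
  optimization (`flownav.experiments`, `flownav.solar`);
* a thin CLI (`flownav steady|sweep|migrate|synthwind|optimize-heading`)
  and narrative scripts under `examples/`.

## Worked example

Crossing a lateral shear flow whose strength reaches 0.8 × self-speed at
the goal line (`python examples/steady_shear.py`):

```
shear flow, W = 0.8 (flow reaches 80% of self-speed at the goal)

strategy     duration efficiency flow support  heading
optimal        1.0901      1.000       -0.083   -27.7 deg
vector         1.0911      0.999       -0.083   -23.6 deg
goal           1.6921      0.644       -0.409    (steered)
fullcomp       1.1586      0.941       -0.137    (steered)

closed forms: T_vector = 1.0911, T_fullcomp = 1.1591
```

Durations are in units of the still-air crossing time, so the optimal
crossing costs 9% extra; its initial heading points 27.7° upstream,
*over*-compensating early to pre-empt the drift that strengthens near
the goal.  Goal orientation drifts first and pays for it (ε = 0.64),
and the numeric durations match the closed forms to ~1e-4.

Other examples: `rotational_benchmark.py` (vector orientation stays
within 10% of optimal at any rotational flow strength),
`feasibility_thresholds.py` (bisection recovers the W = 1 and W = 2
feasibility limits), `synthetic_migration.py` (a 794 km night crossing
through a synthetic cyclone with winds 1.5 × airspeed: optimal and
vector arrive, full compensation and goal orientation fail), and
`seasonal_heading.py` (one compass heading for a season of departures).

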