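"""Vector orientation through rotating flow stays near time-optimal.

Travel crosses a solid-body vortex diametrically, from (0,-1) to (0,1)
in units of the vortex radius.  The flow is balanced along the route, so
simply holding the goalward heading (full drift) exploits the rotation;
the efficiency T*/T^c stays above 0.9 at every flow strength, while full
compensation becomes impossible for W > 1.
"""

from flownav import (
    rotational_durations_closed_form,
    rotational_optimal_duration,
)
from flownav.experiments import rotational_vector_efficiency
from flownav.strategies import ShootingConfig

cfg = ShootingConfig(dt=2e-3, interval_width_deg=2.0)

print(f"{'W':>5} {'T* (optimal)':>13} {'T^c (vector)':>13} {'efficiency':>11} {'T^F (fullcomp)':>15}")
for W in (0.5, 0.8, 1.7, 3.0):
    T_opt, psi0 = rotational_optimal_duration(W)
    pair = rotational_durations_closed_form(W)
    eps = rotational_vector_efficiency(W, cfg)  # by shooting, not closed form
    fc = f"{pair.T_fullcomp:.4f}" if pair.T_fullcomp is not None else "infeasible"
    print(f"{W:5.1f} {T_opt:13.4f} {pair.T_vector:13.4f} {eps:11.4f} {fc:>15}")

print("\nDurations are in units of the still-air crossing time over one")
print("radius (2.0 = still-air value).  Both optimal and vector durations")
print("fall below 2 as W grows: the rotation actively helps, and the")
print("shooting efficiencies agree with the closed forms to ~1e-4.")
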