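"""Recover the shear-flow feasibility limits by bisection.

Full compensation becomes stationary where the lateral flow equals the
self-speed, which first happens at the goal line when W = 1.  A constant
heading must balance the mean drift W/2, which is possible only while
W < 2.  Neither limit is hard-coded: each candidate W is classified by
actually integrating the trajectory (full compensation) or by shooting
over constant headings (vector orientation).
"""

from flownav.experiments import shear_feasibility_threshold
from flownav.strategies import ShootingConfig

w_fc = shear_feasibility_threshold("fullcomp", precision=0.005)
print(f"full compensation remains feasible up to  W = {w_fc:.3f}   (theory: 1)")

cfg = ShootingConfig(dt=4e-3, max_time=20.0, interval_width_deg=2.0)
w_vec = shear_feasibility_threshold("vector", precision=0.005, config=cfg)
print(f"vector orientation remains feasible up to W = {w_vec:.3f}   (theory: 2)")
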