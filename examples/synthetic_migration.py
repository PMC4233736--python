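"""A nocturnal sea crossing through a strong translating cyclone.

A 794 km flight from inland Norway (8.5E, 60N) to the Netherlands
(6E, 53N) at 12 m/s self-speed, departing one hour after civil dusk,
with a synthetic cyclone (peak winds 18 m/s = 1.5x the airspeed)
straddling the route.  Strategies that exploit drift (optimal, vector)
arrive; full compensation hits winds above the airspeed and fails; goal
orientation is blown far off course.
"""

import numpy as np

from flownav import MigrationConfig, SyntheticWindField, TranslatingVortex
from flownav.experiments import run_event
from flownav.solar import departure_after_civil_dusk

config = MigrationConfig(
    start=(8.5, 60.0), goal=(6.0, 53.0), arrival_radius_km=20.0,
    self_speed=12.0, dt_s=180.0, interval_deg=5.0,
)
departure = departure_after_civil_dusk(8.5, 60.0, "2006-10-31")
print(f"departure (civil dusk + 1 h): {np.datetime64(departure, 'm')} UTC")

wind = SyntheticWindField(
    [TranslatingVortex(7.0, 56.5, 18.0, 250.0,
                       t0=departure - np.timedelta64(18, "h"))]
)
results = run_event(config, wind, departure)

print(f"\n{'strategy':<10} {'arrived':>7} {'hours':>7} {'efficiency':>10} {'closest km':>10}")
for name, r in results.items():
    hours = f"{r.duration / 3600:7.1f}" if r.arrived else "      -"
    eff = f"{r.efficiency:10.2f}" if r.arrived else "         -"
    print(f"{name:<10} {str(r.arrived):>7} {hours} {eff} {r.closest_approach:10.0f}")

print("\nEfficiency is travel speed relative to the time-optimal benchmark;")
print("'closest km' is the nearest approach to the goal for failed runs.")
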