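import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_cfg():
    """Planar shooting config used across tests: RK4 at dt=2e-3."""
    from flownav.strategies import ShootingConfig

    return ShootingConfig(dt=2e-3, interval_width_deg=2.0)


@pytest.fixture(scope="session")
def sphere_cfg():
    """Coarse spherical config for short synthetic events."""
    from flownav.sphere import SphereConfig

    return SphereConfig(dt_s=180.0, arrival_radius_km=20.0, interval_width_deg=5.0)


@pytest.fixture(scope="session")
def still_air():
    from flownav.wind import SyntheticWindField, UniformWind

    return SyntheticWindField([UniformWind(0.0, 0.0)])
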