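import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_cell():
    """Catalog geometry 1: the spherical 10 um cell."""
    from rbesim.geometry import get_geometry

    return get_geometry(1)
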