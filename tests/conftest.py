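import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synaptostats3d as s3d

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def box10():
    """10 x 10 x 10 um stack window."""
    return s3d.StackGeometry(10_000.0, 10_000.0, 10_000.0)


@pytest.fixture(scope="session")
def profiles():
    return s3d.load_layer_profiles()


@pytest.fixture(scope="session")
def so_population(box10, profiles):
    """One seeded synthetic population from the SO layer profile."""
    return s3d.generate_population(box10, profiles["SO"], seed=1234)
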