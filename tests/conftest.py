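import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from padsim.params import default_params as dp

    return dp()


@pytest.fixture(scope="session")
def coarse_cable():
    """A cheap cable (coarser discretization) for unit tests; the
    acceptance suite uses the standard d_lambda."""
    from padsim.cable import CableParams, build_cable

    return build_cable(CableParams(d_lambda=0.05))
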