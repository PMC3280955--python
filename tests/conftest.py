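import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_params():
    """Decision-stage parameters on a fast (sigma = 1) scale: first-passage
    times of order 1 ms, so large simulations stay cheap."""
    from fusionddm import StageTwoParams

    return StageTwoParams(a=1.0, z_mean=0.5, sigma=1.0, dt=0.01, t_max=500.0)


@pytest.fixture(scope="session")
def observer():
    """The calibrated millisecond-scale synthetic observer."""
    from fusionddm import default_observer

    return default_observer(0)
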