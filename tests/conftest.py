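import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cryosonic import RewarmSimConfig, simulate_rewarming

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trace_0w():
    """Conduction-only (water bath) rewarming trace, no measurement noise."""
    return simulate_rewarming(RewarmSimConfig(power_w=0.0, noise_sd_c=0.0))


@pytest.fixture(scope="session")
def noiseless_trace_100w():
    """High-power ultrasonic rewarming trace, no measurement noise."""
    return simulate_rewarming(RewarmSimConfig(power_w=100.0, noise_sd_c=0.0))


@pytest.fixture(scope="session")
def noiseless_trace_20w():
    return simulate_rewarming(RewarmSimConfig(power_w=20.0, noise_sd_c=0.0))


def linear_trace(rate_c_per_s=1.0, t0=-65.0, t_end=10.0, dt=0.5, power=0.0):
    """A perfectly linear warming trace used as an analytic reference."""
    from cryosonic import TemperatureTrace

    n = int(np.ceil((t_end - t0) / rate_c_per_s / dt)) + 1
    t = dt * np.arange(n)
    return TemperatureTrace(times_s=t, temperatures_c=t0 + rate_c_per_s * t, power_w=power)
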