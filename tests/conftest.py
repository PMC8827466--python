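import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modalage.curves import survival_and_density

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the reference adult Gompertz hazard used throughout the oracle tests
GOMPERTZ_A = 1.068e-5
GOMPERTZ_B = 0.11


def fine_grid(lo=31.0, hi=110.0, step=0.01):
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


@pytest.fixture(scope="session")
def gompertz_smooth():
    """Analytic Gompertz hazard completed into survival and density."""
    x = fine_grid()
    mu = GOMPERTZ_A * np.exp(GOMPERTZ_B * x)
    return survival_and_density(x, mu, stratum="gompertz", year=2000)


@pytest.fixture(scope="session")
def constant_smooth():
    """Constant hazard 0.05/yr: exponential lifetimes, analytic everything."""
    x = fine_grid()
    return survival_and_density(x, np.full_like(x, 0.05), stratum="const", year=2000)
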