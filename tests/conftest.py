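import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tocsim import CostModel, Population, ProductivityModel, grid_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp_model():
    return ProductivityModel.exponential()


@pytest.fixture(scope="session")
def grid50():
    """The reference scenario: 50 agents, c_i = 0.15 + 0.002 i."""
    return grid_population(0.15, 0.002, 50)


@pytest.fixture(scope="session")
def grid50_oligarch():
    return grid_population(0.15, 0.002, 50, oligarch_c=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230208)


def bisect_total_investment(N, c_mean, lo=0.0, hi=None, iters=200):
    """Independent bisection oracle for (1 - x/N) e^{-x} = c_mean."""
    hi = float(N) if hi is None else hi
    f = lambda x: (1.0 - x / N) * np.exp(-x) - c_mean
    assert f(lo) > 0 > f(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def bisection_oracle():
    return bisect_total_investment
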