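import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def analytic_pr():
    """Log-space closed-form retention used as a scalar oracle in tests."""

    def _pr(theta, nu, tau, eta_max, L=1000.0):
        from embersim import discontinuity_probability

        p_d = discontinuity_probability(theta, nu, tau, eta_max)
        if p_d >= 1.0:
            return 0.0
        return math.exp((L / theta) * math.log1p(-p_d))

    return _pr
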