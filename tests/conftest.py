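import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrmediate import HarmonizedInstruments

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_h():
    """Factory for HarmonizedInstruments from plain arrays."""

    def _make(beta_exp, se_exp, beta_out, se_out, **kw):
        return HarmonizedInstruments.from_arrays(beta_exp, se_exp, beta_out, se_out, **kw)

    return _make


@pytest.fixture
def random_h(make_h):
    """Seeded generator of valid random instrument sets."""

    def _gen(seed, J=10, beta=0.3, pleiotropy_sd=0.0):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.2, J)
        sx = rng.uniform(0.005, 0.02, J)
        sy = rng.uniform(0.02, 0.1, J)
        alpha = rng.normal(0, pleiotropy_sd, J) if pleiotropy_sd else 0.0
        by = beta * bx + alpha + sy * rng.standard_normal(J)
        bxh = bx + sx * rng.standard_normal(J)
        return _make_valid(make_h, bxh, sx, by, sy)

    def _make_valid(make, bx, sx, by, sy):
        bx = np.where(bx == 0, 1e-6, bx)
        return make(bx, sx, by, sy)

    return _gen
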