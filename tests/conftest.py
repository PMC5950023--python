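import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aaasim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def naaasp_bundle():
    return aaasim.load_bundle("naaasp-basecase")


@pytest.fixture(scope="session")
def mass_bundle():
    return aaasim.load_bundle("mass-validation")


@pytest.fixture(scope="session")
def means_draw(naaasp_bundle):
    return aaasim.fix_bundle_at_means(naaasp_bundle)


@pytest.fixture(scope="session")
def mass_means_draw(mass_bundle):
    return aaasim.fix_bundle_at_means(mass_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
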