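import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_scheme():
    """The full acquisition geometry: 30 directions, 3 shells, 5 b0."""
    from dkiblast import make_scheme

    return make_scheme(30, [1000, 1500, 2000], 5, seed=1)


@pytest.fixture(scope="session")
def small_scheme():
    from dkiblast import make_scheme

    return make_scheme(12, [1000, 2000], 2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
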