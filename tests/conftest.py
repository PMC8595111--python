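import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from oddballerp import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def templates():
    return syn.default_templates()


@pytest.fixture(scope="session")
def treatments():
    return syn.default_treatments()


@pytest.fixture()
def small_cohort():
    """Two-animal, 30-stimulus cohort for fast structural tests."""
    return syn.CohortSpec(n_animals=2, n_standard=26, n_deviant=4,
                          seed=11, artifact_rate=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
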