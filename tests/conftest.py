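import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_config():
    from asthmace import load_example_config

    return load_example_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250929)


def random_transition_matrix(rng):
    """A random valid 4x4 weekly matrix with absorbing death."""
    from asthmace import TransitionMatrix

    P = np.zeros((4, 4))
    for i in range(3):
        row = rng.dirichlet(np.ones(4) * rng.uniform(0.5, 3.0))
        P[i] = row
    P[3, 3] = 1.0
    return TransitionMatrix(P)
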