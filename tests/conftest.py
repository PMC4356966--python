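import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_symmetric(rng, n, scale=0.5):
    G = rng.normal(scale=scale, size=(n, n))
    return (G + G.T) / 2.0


def random_model(rng, n, scale=0.5):
    from lowrank_ising import IsingModel

    return IsingModel(b=rng.normal(scale=scale, size=n), A=random_symmetric(rng, n, scale))
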