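import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sin_scheme():
    from rotafret.synthetic_traces import KineticScheme

    return KineticScheme.preset("sin37")


@pytest.fixture(scope="session")
def sin_emission():
    from rotafret.synthetic_traces import EmissionModel

    return EmissionModel.preset("sin37")


@pytest.fixture(scope="session")
def small_sin_dataset(sin_scheme, sin_emission):
    """30 Sin-parameterized traces with ground truth, reused across tests."""
    from rotafret.synthetic_traces import generate_dataset

    return generate_dataset(
        sin_scheme, sin_emission, 30, 25.0, seed=424242, donor_only_fraction=0.1
    )
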