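import numpy as np
import pytest

from twopathway.patterns import generate_patterns


@pytest.fixture(scope="session")
def small_ensemble():
    """A small single-pathway task shared by cheap unit tests."""
    return generate_patterns(P=20, N_x=50, N_y=0, N_z=1, seed=123)


@pytest.fixture(scope="session")
def two_pathway_ensemble():
    return generate_patterns(P=20, N_x=40, N_y=30, N_z=1, seed=321)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
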