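import numpy as np
import pytest
from hypothesis import settings

from mitohet.reference import mini_reference, synthetic_full_reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mini_ref():
    return mini_reference()


@pytest.fixture(scope="session")
def full_ref():
    """Full-size (16,569 bp) synthetic genome with the standard region layout."""
    return synthetic_full_reference(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
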