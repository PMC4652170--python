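import numpy as np
import pytest

from bivalscan import synthetic_data as sd


@pytest.fixture(scope="session")
def small_ref():
    """A 200-promoter synthetic reference shared by sequence-level tests."""
    return sd.simulate_reference(n_promoters=200, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_ref):
    return small_ref.truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
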