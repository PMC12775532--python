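import numpy as np
import pytest

from refcoh.simulate import small_config, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Desk-scale synthetic corpus shared by read-only tests."""
    return simulate_corpus(small_config(seed=11), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
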