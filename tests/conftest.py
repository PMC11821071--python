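import numpy as np
import pytest

from fgdae import SynthConfig, make_synthetic_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small synthetic pair sets shared across tests (64 train / 32 test)."""
    return make_synthetic_benchmark(SynthConfig(), n_train=64, n_test=32, seed=11)
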