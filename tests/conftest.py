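import numpy as np
import pytest

from neurocomplexity.synth import gen_modular_connectome


@pytest.fixture(scope="session")
def small_connectome():
    """A 10-node, 2-module connectome for fast simulator tests."""
    return gen_modular_connectome(n_nodes=10, n_modules=2, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
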