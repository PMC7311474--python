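import numpy as np
import pytest

from scapa.synthetic import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 40-gene simulated genome shared by read-level tests."""
    return simulate_genome(SimConfig(seed=11, n_genes=40))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
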