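import numpy as np
import pytest

from mirmatch.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """One small fully simulated dataset shared across read-only tests."""
    cfg = SimConfig(n_genes=150, n_mirnas=4, rng_seed=11)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
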