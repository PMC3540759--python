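import numpy as np
import pytest

from lepnet.simulate import gen_sigma_expdecay, sample_mvn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20121223)


@pytest.fixture(scope="session")
def chain_data():
    """n=120 draw from a p=10 exponential-decay (chain) truth."""
    truth = gen_sigma_expdecay(p=10, seed=5)
    X = sample_mvn(truth, n=120, seed=7)
    return truth, X


@pytest.fixture(scope="session")
def small_gauss(rng):
    """Small i.i.d. Gaussian matrix (p=5 genes, n=40 samples)."""
    return rng.standard_normal((5, 40))
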