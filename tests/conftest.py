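import numpy as np
import pytest

from amvml import make_block_instance


@pytest.fixture(scope="session")
def tiny_instance():
    """Small block instance for loops that refit the model many times."""
    return make_block_instance(q=12, p=15, n_disease_groups=2, n_mirna_groups=3,
                               within_prob=0.9, between_prob=0.05,
                               density_scale=0.6, seed=11)


@pytest.fixture(scope="session")
def default_instance():
    """The default study-condition instance (60 x 80, 3 x 4 blocks)."""
    return make_block_instance(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
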