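import numpy as np
import pytest

from dnahyb import dataset as dsm
from dnahyb import seqops


@pytest.fixture(scope="session")
def small_dataset():
    """~1.5k builtin-oracle pairs with splits, shared across tests."""
    ds = dsm.assemble_dataset(seed_count=20, target_size=1200, rng_seed=101)
    return dsm.stratified_split(ds, rng_seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_pairs():
    """200 random full-length sequence pairs (18-26 nt)."""
    gen = np.random.default_rng(7)
    return [(seqops.random_seed_sequence(gen), seqops.random_seed_sequence(gen))
            for _ in range(200)]
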