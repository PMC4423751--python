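import numpy as np
import pytest

from seedwave import FMIndex, Reference
from seedwave.simulate import generate_genome, identity_donor


@pytest.fixture(scope="session")
def small_ref():
    return Reference([("c1", "GATTACAGATTACACATTAG")])


@pytest.fixture(scope="session")
def small_index(small_ref):
    return FMIndex.build(small_ref, occ_rate=4, sa_rate=2)


@pytest.fixture(scope="session")
def genome_100k():
    return generate_genome(100_000, n_contigs=1, gc=0.41, rng_seed=11)


@pytest.fixture(scope="session")
def index_100k(genome_100k):
    return FMIndex.build(genome_100k)


@pytest.fixture(scope="session")
def donor_100k(genome_100k):
    return identity_donor(genome_100k)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
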