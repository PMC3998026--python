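import numpy as np
import pytest

import codonchannel as cc


@pytest.fixture(scope="session")
def code():
    return cc.standard_code()


@pytest.fixture(scope="session")
def bio64():
    """Biological codon frequencies over all 64 codons (renormalized)."""
    return cc.load_biological_codon_frequencies()


@pytest.fixture(scope="session")
def bio61(code, bio64):
    """Biological frequencies restricted to the 61 sense codons."""
    return bio64.restrict(code.sense_order)


@pytest.fixture(scope="session")
def opt61(code, bio61):
    """Capacity-achieving codon frequencies, aligned to the sense order."""
    return cc.load_capacity_achieving_codon_frequencies().reorder(bio61.labels)


@pytest.fixture()
def bsc11():
    channel, capacity = cc.make_binary_symmetric_channel(0.11)
    return channel, capacity


def random_simplex(rng, n):
    return rng.dirichlet(np.ones(n))
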