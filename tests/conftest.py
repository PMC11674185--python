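import numpy as np
import pytest

from tailscope import simulate
from tailscope.seqio import Read

ADAPTER = "CTGTAGGCACCATCAATTCGT"  # 21 nt, arbitrary fixture adapter


@pytest.fixture(scope="session")
def adapter():
    return ADAPTER


@pytest.fixture(scope="session")
def reference():
    """A 300 nt synthetic amplicon reference with no >=8 nt A-run."""
    return simulate.gen_reference(length=300, gc_fraction=0.5, seed=11)


def make_read(name, seq, qual=38):
    """Build a Read with a flat quality profile."""
    return Read(name, seq, tuple([qual] * len(seq)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
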