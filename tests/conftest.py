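import numpy as np
import pytest

from mirnaloc.properties import load_default_table, standardize
from mirnaloc.sequence_io import RnaSequence

BASES = "ACGU"


@pytest.fixture(scope="session")
def raw_table():
    return load_default_table()


@pytest.fixture(scope="session")
def std_table(raw_table):
    return standardize(raw_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length=22, sid="r"):
    return RnaSequence(id=sid, residues="".join(rng.choice(list(BASES), size=length)))


@pytest.fixture
def random_seqs(rng):
    return [random_sequence(rng, length=int(rng.integers(18, 26)), sid=f"r{i}") for i in range(30)]
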