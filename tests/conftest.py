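import numpy as np
import pytest

from graspmine.seqcore import AMINO_ACIDS, SubstitutionMatrix


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


@pytest.fixture()
def make_protein(rng):
    def _make(n):
        return random_protein(rng, n)

    return _make
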