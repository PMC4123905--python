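import random

import numpy as np
import pytest

from sufseek.scoring import RESIDUES, load_score_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_score_matrix("BLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(20140806)


def random_protein(rng, n, alphabet=RESIDUES):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


@pytest.fixture()
def random_protein_factory(rng):
    def make(n, alphabet=RESIDUES):
        return random_protein(rng, n, alphabet)
    return make
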