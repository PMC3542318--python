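import numpy as np
import pytest

from amylcons.fixtures import FixtureSpec, generate
from amylcons.model import ProteinSequence

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """200 random standard-alphabet sequences of length 6..100."""
    seqs = []
    for i in range(200):
        n = int(rng.integers(6, 101))
        residues = "".join(rng.choice(list(STANDARD_AA), size=n))
        seqs.append(ProteinSequence(f"r{i}", residues))
    return seqs


@pytest.fixture(scope="session")
def planted_fixture():
    return generate(FixtureSpec(seed=7, n_sequences=6, length=80))
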