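import numpy as np
import pytest

from pssmbind.core_scoring import AMINO_ACIDS, BackgroundFrequencies


@pytest.fixture(scope="session")
def background():
    return BackgroundFrequencies.default()


@pytest.fixture(scope="session")
def uniform_background():
    """Uniform background (every residue at 0.05); makes hand arithmetic exact."""
    return BackgroundFrequencies(dict.fromkeys(AMINO_ACIDS, 0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_peptides(rng, n, length):
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(letters[rng.integers(20, size=length)]) for _ in range(n)]
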