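import numpy as np
import pytest

from uzonmlsa import load_uzon_fixture


@pytest.fixture(scope="session")
def uzon():
    return load_uzon_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20130169)


def random_sequences(rng, n, length, missing_frac=0.0):
    """Random aligned nucleotide strings, optionally sprinkled with missing data."""
    alphabet = np.array(list("ACGT"))
    mat = alphabet[rng.integers(0, 4, size=(n, length))]
    if missing_frac:
        mask = rng.random((n, length)) < missing_frac
        fill = np.array(list("N-"))[rng.integers(0, 2, size=(n, length))]
        mat = np.where(mask, fill, mat)
    return ["".join(row) for row in mat]
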