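import numpy as np
import pytest

from crfgwas.datatypes import GenotypeMatrix, PhenotypeVector


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n, p=2, coupling_sd=0.15):
    """Small random CRF instance: design, weights, symmetric couplings, labels."""
    X = rng.standard_normal((n, p))
    w = rng.normal(0, 0.5, p)
    A = rng.normal(0, coupling_sd, (n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    y = rng.integers(0, 2, n)
    return X, w, A, y


@pytest.fixture()
def small_genotypes(rng):
    vals = rng.integers(0, 3, (6, 8)).astype(np.int8)
    return GenotypeMatrix(values=vals)


@pytest.fixture()
def binary_labels(rng):
    return PhenotypeVector(labels=rng.integers(0, 2, 6))
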