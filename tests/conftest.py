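import numpy as np
import pytest

from mlabdna import SimConfig, simulate


@pytest.fixture(scope="session")
def small_corpus():
    """12 short proteins with the default signal, shared across tests."""
    return simulate(SimConfig(n_proteins=12, length_range=(40, 60), seed=42))


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    return small_corpus.to_dataset(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def separable_blobs():
    """Two tight, well-separated 2-D classes: 20 training + 20 test points."""
    gen = np.random.default_rng(7)
    centers = {0: np.array([3.0, 0.0]), 1: np.array([0.0, 3.0])}
    Xtr, ytr, Xte, yte = [], [], [], []
    for label, c in centers.items():
        Xtr.append(c + 0.25 * gen.normal(size=(10, 2)))
        Xte.append(c + 0.25 * gen.normal(size=(10, 2)))
        ytr += [label] * 10
        yte += [label] * 10
    return (
        np.concatenate(Xtr),
        np.array(ytr),
        np.concatenate(Xte),
        np.array(yte),
    )
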