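import numpy as np
import pytest

from ddsr.sparse_coding import Dictionary


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ortho_dictionary():
    """Three orthonormal atoms, one per class 1..3."""
    atoms = np.eye(3)
    return Dictionary(atoms=atoms, class_codes=np.array([1, 2, 3]))


def random_unit(rng, n):
    v = rng.normal(size=n)
    return v / np.linalg.norm(v)


def random_dictionary(rng, n_atoms, bands, n_classes=None):
    """Random unit-norm dictionary with contiguous ascending class codes."""
    n_classes = n_classes or n_atoms
    atoms = np.array([random_unit(rng, bands) for _ in range(n_atoms)])
    codes = np.sort(rng.integers(1, n_classes + 1, size=n_atoms))
    return Dictionary(atoms=atoms, class_codes=codes)
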