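import numpy as np
import pandas as pd
import pytest

from samblup.params import duroc_reference_components
from samblup.pedigree import Pedigree


@pytest.fixture(scope="session")
def ref_vc():
    """Posterior-mean Duroc SAM components (the generating truth)."""
    return duroc_reference_components()


@pytest.fixture
def trio_ped():
    return Pedigree(np.array([0, 0, 1]), np.array([0, 0, 2]))


@pytest.fixture
def toy_ped():
    """10 animals: 4 founders, full sibs, an inbred tail."""
    sire = np.array([0, 0, 0, 0, 1, 1, 3, 3, 1, 3])
    dam = np.array([0, 0, 0, 0, 2, 2, 4, 4, 4, 2])
    return Pedigree(sire, dam)


@pytest.fixture
def toy_data(toy_ped):
    """Two-trait records for the 10-animal toy (2 pens, 2 batches)."""
    rng = np.random.default_rng(42)
    y = rng.normal(size=(10, 2)) * [0.8, 3.0]
    return pd.DataFrame({
        "animal": np.arange(1, 11),
        "batch": [0] * 5 + [1] * 5,
        "pen": [0] * 5 + [1] * 5,
        "litter": [0, 0, 1, 1, 2, 2, 0, 1, 2, 0],
        "adg": y[:, 0],
        "bf": y[:, 1],
    })


def random_pedigree(n, n_founders, seed):
    """Random sorted pedigree: sires from the first half, dams the second."""
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        sire[i] = rng.integers(1, max(2, i // 2))
        dam[i] = rng.integers(max(1, i // 2), i)
    return Pedigree(sire, dam)
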