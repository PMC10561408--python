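import numpy as np
import pytest
import scipy.sparse as sp

from atacdoublets import fixtures_eval
from atacdoublets.matrix_io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_count_matrix(rng, n=20, p=40, density=0.3, max_count=5):
    """Random sparse integer CountMatrix with positive row/col sums."""
    vals = rng.integers(0, max_count + 1, size=(n, p))
    vals[rng.random((n, p)) > density] = 0
    # guarantee positive row and column sums
    for i in range(n):
        if vals[i].sum() == 0:
            vals[i, rng.integers(p)] = 1
    for j in range(p):
        if vals[:, j].sum() == 0:
            vals[rng.integers(n), j] = 1
    return CountMatrix(
        sp.csr_matrix(vals),
        np.array([f"bc{i}" for i in range(n)], dtype=object),
        np.array([f"pk{j}" for j in range(p)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_planted():
    """Small planted benchmark in the standard regime (depth = 0.02 * peaks)."""
    ds = fixtures_eval.generate_singlets(
        n_singlets=240, n_types=3, proportions=(0.5, 0.3, 0.2),
        n_peaks=3000, mean_depth=60.0, specificity=0.8, seed=5)
    return fixtures_eval.plant_doublets(ds, doublet_rate=0.2, weighted=True,
                                        seed=6)


@pytest.fixture(scope="session")
def two_block_types():
    """Two cell types with disjoint accessible-peak blocks; known labels."""
    ds = fixtures_eval.generate_singlets(
        n_singlets=120, n_types=2, proportions=(0.5, 0.5),
        n_peaks=800, mean_depth=40.0, specificity=1.0, seed=3)
    return ds
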