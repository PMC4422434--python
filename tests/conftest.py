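import numpy as np
import pytest

from cpo import DietMatrix


@pytest.fixture
def small_diet():
    """6 species x 4 prey counts used across the CCA tests (the same
    table was fed to an independent CCA implementation to freeze oracle
    values)."""
    counts = np.array([
        [5, 1, 0, 2],
        [4, 2, 1, 0],
        [0, 6, 2, 1],
        [1, 5, 3, 0],
        [2, 1, 7, 4],
        [0, 2, 5, 6],
    ], dtype=float)
    return DietMatrix(
        species_ids=[f"s{i}" for i in range(6)],
        prey_categories=list("abcd"),
        counts=counts,
    )


@pytest.fixture
def small_design():
    """Two binary constraint columns and one numeric covariate aligned to
    ``small_diet``."""
    X = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0, 0], [0, 0]], dtype=float)
    z = np.array([0.3, 1.2, -0.5, 0.8, 2.0, -1.1])[:, None]
    return X, z


def random_count_matrix(rng, min_n=3, max_n=12, min_m=2, max_m=6):
    """Random nonnegative count matrix with no zero row or column."""
    while True:
        n = int(rng.integers(min_n, max_n + 1))
        m = int(rng.integers(min_m, max_m + 1))
        counts = rng.poisson(2.0, size=(n, m)).astype(float)
        if np.all(counts.sum(axis=1) > 0) and np.all(counts.sum(axis=0) > 0):
            return counts
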