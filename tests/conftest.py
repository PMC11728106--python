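import numpy as np
import pytest

from lfqimpute import (IntensityMatrix, MissingnessSpec, SyntheticSpec,
                       apply_missingness, generate_complete_matrix)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_proteins=100, seed=11)


@pytest.fixture
def small_complete(small_spec):
    matrix, truth = generate_complete_matrix(small_spec)
    return matrix, truth


@pytest.fixture
def masked_dataset(small_complete):
    matrix, _ = small_complete
    return apply_missingness(matrix, MissingnessSpec(alpha=0.25, beta=0.8, seed=7))


def random_incomplete_matrix(rng, n=30, p=8, missing_fraction=0.2, scale="log2"):
    """Small log2-scale matrix with uniform random missingness, guarding
    against empty rows/columns."""
    values = rng.normal(25.0, 2.0, size=(n, p))
    n_miss = int(missing_fraction * n * p)
    cells = rng.choice(n * p, size=n_miss, replace=False)
    flat = values.ravel()
    flat[cells] = np.nan
    values = flat.reshape(n, p)
    # ensure every row and column keeps at least one observed cell
    for i in range(n):
        if np.isnan(values[i]).all():
            values[i, rng.integers(p)] = rng.normal(25.0, 2.0)
    for j in range(p):
        if np.isnan(values[:, j]).all():
            values[rng.integers(n), j] = rng.normal(25.0, 2.0)
    groups = ["control"] * (p // 2) + ["treated"] * (p - p // 2)
    return IntensityMatrix(values, [f"P{i}" for i in range(n)],
                           [f"s{j}" for j in range(p)], groups, scale=scale)
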