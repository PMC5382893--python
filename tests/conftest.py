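import numpy as np
import pytest

from ecofilter.matrix_io import InteractionMatrix


def make_matrix(values, name="test") -> InteractionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return InteractionMatrix(
        values=values,
        row_labels=[f"R{i+1}" for i in range(n)],
        col_labels=[f"C{j+1}" for j in range(m)],
        name=name,
    )


def random_matrix(rng, n, m, density=0.5, weighted=True) -> InteractionMatrix:
    values = np.zeros(n * m)
    k = max(1, min(n * m - 1, int(round(density * n * m))))
    cells = rng.choice(n * m, size=k, replace=False)
    values[cells] = rng.uniform(0.1, 5.0, size=k) if weighted else 1.0
    return make_matrix(values.reshape(n, m), name=f"random-{n}x{m}")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def staircase10():
    """Perfectly nested 10x10 staircase (row i has 10-i leading positives)."""
    values = np.zeros((10, 10))
    for i in range(10):
        values[i, : 10 - i] = 1.0
    return make_matrix(values, name="staircase10")


@pytest.fixture
def small_fixture_suite(rng):
    """Small matrices (<= 8x8), binary and weighted, for oracle sweeps."""
    suite = [
        make_matrix([[1.0, 0.0], [0.0, 0.0]], name="one-positive-2x2"),
        make_matrix(
            [[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], name="nested-3x4"
        ),
    ]
    for k, (n, m, density, weighted) in enumerate(
        [(4, 5, 0.4, False), (6, 6, 0.3, True), (8, 7, 0.2, False), (8, 8, 0.5, True)]
    ):
        suite.append(random_matrix(rng, n, m, density, weighted))
    return suite
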