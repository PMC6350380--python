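import numpy as np
import pytest

from wtofid import ExpressionMatrix, WeightMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_matrix():
    """A 4-gene × 5-sample matrix with known values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 1.0, 4.0, 3.0, 6.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [1.0, 1.0, 2.0, 2.0, 3.0],
        ]
    )
    return ExpressionMatrix(["a", "b", "c", "d"], ["s1", "s2", "s3", "s4", "s5"], values)


def random_weight_matrix(n: int, rng: np.random.Generator) -> WeightMatrix:
    """Random symmetric weight matrix in [0, 1] with zero diagonal."""
    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return WeightMatrix([f"g{i}" for i in range(n)], A)
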