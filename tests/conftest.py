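import numpy as np
import pytest

from sagat import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_ids=None, array_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"G{i}" for i in range(n)],
        array_ids or [f"A{j}" for j in range(m)],
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
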