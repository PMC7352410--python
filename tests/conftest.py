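import numpy as np
import pandas as pd
import pytest

from pmprisk import ExpressionMatrix
from pmprisk.expression_io import LINEAR


@pytest.fixture
def rng():
    return np.random.default_rng(20200612)


@pytest.fixture
def small_linear_matrix():
    """5 genes x 4 samples, strictly positive linear signals."""
    values = pd.DataFrame(
        {
            "s1": [100.0, 50.0, 10.0, 400.0, 8.0],
            "s2": [200.0, 25.0, 10.0, 400.0, 8.0],
            "s3": [100.0, 50.0, 40.0, 100.0, 8.0],
            "s4": [400.0, 100.0, 20.0, 800.0, 16.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(values, LINEAR)


@pytest.fixture
def random_linear_matrix(rng):
    n_genes, n_samples = 60, 8
    values = pd.DataFrame(
        np.exp2(rng.normal(7, 1, size=(n_genes, n_samples))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values, LINEAR)
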