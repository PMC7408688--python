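import numpy as np
import pandas as pd
import pytest

from brainsig import ExpressionMatrix, default_group_assignment


@pytest.fixture
def groups():
    return default_group_assignment()


@pytest.fixture
def random_matrix(groups):
    """A 500 x 9 iid-normal log2 matrix on the nine cell-line samples."""

    def make(seed: int, n_genes: int = 500) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.normal(8.0, 2.0, (n_genes, 9)),
            index=[f"G{i:04d}" for i in range(n_genes)],
            columns=groups.samples,
        )
        return ExpressionMatrix(data, level="gene")

    return make
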