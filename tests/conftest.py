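import numpy as np
import pandas as pd
import pytest

from crosspath import ExpressionMatrix


def make_matrix(values, scale="log2", n_disease=None, prefix="s"):
    """Small ExpressionMatrix from a 2-D array; first half of the columns
    (or n_disease of them) are the disease class."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    if n_disease is None:
        n_disease = n_cols // 2
    samples = [f"{prefix}{i}" for i in range(n_cols)]
    pheno = pd.Series(
        ["disease"] * n_disease + ["control"] * (n_cols - n_disease), index=samples
    )
    df = pd.DataFrame(values, index=[f"r{i}" for i in range(n_rows)], columns=samples)
    return ExpressionMatrix(df, scale, pheno, ("disease", "control"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
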