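import numpy as np
import pandas as pd
import pytest

from plastinet.io import ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 naive / 2 plastic, handmade values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 2.5, 5.0, 5.5],
         [10.0, 9.0, 1.0, 2.0]],
        index=["p1", "p2", "p3"],
        columns=["n1", "n2", "x1", "x2"],
    )
    groups = pd.Series(["naive", "naive", "plastic", "plastic"],
                       index=values.columns)
    return ExpressionMatrix(values, groups, "raw")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
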