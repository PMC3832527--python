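import numpy as np
import pandas as pd
import pytest

from tagdge.io_formats import ExpressionMatrix

TWO_BY_TWO_DESIGN = {"G1": "G", "G2": "G", "M1": "M", "M2": "M"}


def make_matrix(rows: dict[str, list[int]], size_factors=None) -> ExpressionMatrix:
    """Build a 2x2-design ExpressionMatrix from per-gene count lists."""
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(TWO_BY_TWO_DESIGN))
    return ExpressionMatrix(
        counts=counts, design=dict(TWO_BY_TWO_DESIGN), size_factors=size_factors
    )


@pytest.fixture
def worked_matrix() -> ExpressionMatrix:
    """The hand-worked single-gene example: G replicates 20,20; M 10,10."""
    return make_matrix({"g1": [20, 20, 10, 10]})


@pytest.fixture
def random_counts() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(30, size=(50, 4)),
        index=[f"g{i}" for i in range(50)],
        columns=list(TWO_BY_TWO_DESIGN),
    )
    return counts
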