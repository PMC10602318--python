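import numpy as np
import pandas as pd
import pytest

from methylsink import CountMatrix, ExpressionMatrix, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """4 genes x 6 samples, two cohorts, all counts positive."""
    counts = pd.DataFrame(
        [
            [10, 20, 30, 12, 24, 36],
            [100, 200, 300, 90, 180, 270],
            [50, 55, 60, 45, 50, 61],
            [5, 8, 12, 6, 9, 11],
        ],
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(6)],
    )
    metadata = pd.DataFrame(
        {
            "cohort": ["A", "A", "A", "B", "B", "B"],
            "donor": ["d1", "d2", "d3", "d1", "d4", "d5"],
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, metadata=metadata)


@pytest.fixture
def random_expr(rng):
    """50 genes x 40 samples of positive pseudocounts."""
    vals = rng.lognormal(mean=4.0, sigma=0.5, size=(50, 40))
    df = pd.DataFrame(
        vals,
        index=[f"g{i:02d}" for i in range(50)],
        columns=[f"s{i:02d}" for i in range(40)],
    )
    return ExpressionMatrix(values=df, transform="pseudocount")


@pytest.fixture
def toy_gene_set():
    return GeneSet(name="toy", members=["g00", "g01", "g02"])
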