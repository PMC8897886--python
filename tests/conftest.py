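import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from drga.io import AlignedDataset, ClinicalTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_expression():
    """5 genes x 6 samples, deterministic, non-constant."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(size=(5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def aligned(small_expression):
    """Aligned dataset with two continuous features, one categorical, and survival."""
    rng = np.random.default_rng(7)
    n = len(small_expression.sample_ids)
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "age": rng.normal(60, 10, n),
                "marker": rng.lognormal(size=n),
                "stage": ["I", "II", "I", "III", "II", "I"],
            },
            index=small_expression.sample_ids,
        ),
        {"age": "continuous", "marker": "continuous", "stage": "categorical"},
        pd.Series(rng.exponential(10, n), index=small_expression.sample_ids),
        pd.Series([1.0, 0.0, 1.0, 1.0, 0.0, 1.0], index=small_expression.sample_ids),
    )
    return AlignedDataset(small_expression, clin, small_expression.gene_ids)
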