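import numpy as np
import pandas as pd
import pytest

from egfr_impact import ExpressionMatrix, SyntheticSpec, generate_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 3 samples with distinct values in every column."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(4, 3)),
        index=["a", "b", "c", "d"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def two_group_matrix():
    """50 genes x 20 samples, 10 per group, with boolean labels."""
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(20)]
    data = pd.DataFrame(
        rng.normal(7.0, 0.8, size=(50, 20)),
        index=[f"g{i}" for i in range(50)],
        columns=samples,
    )
    labels = pd.Series([True] * 10 + [False] * 10, index=samples)
    return ExpressionMatrix(data), labels


@pytest.fixture
def default_cohort():
    return generate_cohort(SyntheticSpec(seed=3))
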