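import numpy as np
import pandas as pd
import pytest

from disulfiscore import (
    ExpressionMatrix,
    SimulationConfig,
    bundled_regulators,
    simulate_bulk_contrast,
)


@pytest.fixture(scope="session")
def regulators():
    return bundled_regulators()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_expr(rng):
    """20 genes x 3 samples random matrix with named genes."""
    genes = [f"G{i:02d}" for i in range(20)]
    values = rng.lognormal(1.0, 1.0, (20, 3))
    df = pd.DataFrame(values, index=genes, columns=["s1", "s2", "s3"])
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def contrast_matrix():
    """Default-condition two-group contrast: +1 log2 on the positive set."""
    return simulate_bulk_contrast(SimulationConfig(seed=1))
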