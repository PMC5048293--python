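import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exprest.io_formats import ExpressionMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """4 genes x 5 samples with simple structure around a seed gene."""
    rng = np.random.default_rng(7)
    seed = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    df = pd.DataFrame(
        [seed, 2 * seed + 1, -seed + 10, rng.normal(size=5)],
        index=["REST", "POSG", "NEGG", "RANDG"],
        columns=[f"s{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
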