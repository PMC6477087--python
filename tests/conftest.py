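import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncscope.types import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with known group means."""
    values = pd.DataFrame(
        {
            "T1": [8.0, 2.0, 0.0],
            "T2": [8.0, 2.0, 0.0],
            "C1": [2.0, 2.0, 0.0],
            "C2": [2.0, 2.0, 0.0],
        },
        index=["G_UP", "G_FLAT", "G_ZERO"],
    )
    groups = {"T1": "tumor", "T2": "tumor", "C1": "control", "C2": "control"}
    return ExpressionMatrix(values, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
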