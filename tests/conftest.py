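import warnings

import numpy as np
import pandas as pd
import pytest

from hetmob.imputation import ImputedStack
from hetmob.synthetic import SyntheticConfig, generate_trial_pair


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic two-trial dataset (N=504, complete outcome)."""
    return generate_trial_pair(SyntheticConfig(seed=11))


@pytest.fixture
def tiny_table():
    """Hand-built 10-row participant-like table with known change scores."""
    rng = np.random.default_rng(0)
    n = 10
    return pd.DataFrame(
        {
            "trial": ["trial_A"] * 5 + ["trial_B"] * 5,
            "arm": ["control", "intervention"] * 5,
            "phq9_baseline": [10, 12, 8, 15, 9, 11, 14, 7, 10, 13],
            "phq9_post": [9, 6, 8, 10, 9, 10, 7, 7, 8, 6],
            "pseq": [30, 40, 35, 20, 45, 38, 25, 50, 33, 28],
            "age": rng.integers(30, 70, n),
        }
    )


def wrap_stack(table: pd.DataFrame) -> ImputedStack:
    """Minimal single-imputation stack around a complete table."""
    return ImputedStack(
        tables=[table.reset_index(drop=True)],
        predictor_matrix=pd.DataFrame(),
        methods={},
        trace=pd.DataFrame(),
        missing_mask=pd.DataFrame(index=table.reset_index(drop=True).index),
    )


@pytest.fixture
def stack_of(default_table):
    return wrap_stack(default_table)
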