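import numpy as np
import pandas as pd
import pytest

from bfagree.cohort import default_config, simulate_cohort
from bfagree.pipeline import add_panel_columns


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 2,000-subject synthetic cohort with BF% panels, shared across tests."""
    frame = simulate_cohort(default_config(n=2000, seed=42))
    return add_panel_columns(frame)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
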