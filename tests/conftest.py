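import numpy as np
import pandas as pd
import pytest

from imputevar.dgp import IncompleteDataset, apply_mdm, generate_complete, scenario_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture
def six_row_data():
    """Tiny fixed dataset with two of six weight values missing."""
    frame = pd.DataFrame(
        {
            "sex": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "age": [24.1, 25.3, 26.0, 24.8, 25.5, 23.9],
            "height": [1.80, 1.65, 1.75, 1.60, 1.82, 1.70],
            "weight": [82.0, 61.5, np.nan, 58.0, np.nan, 66.0],
            "loginsindex": [4.9, 4.1, 5.2, 3.9, 5.0, 4.3],
        }
    )
    return IncompleteDataset.from_frame(frame, "weight")


@pytest.fixture
def small_incomplete(rng):
    """A subgroup-preset dataset at n=200 with weight missing in men."""
    cfg = scenario_config("subgroup", n=200, p_obs=0.5)
    complete = generate_complete(cfg, rng)
    return cfg, apply_mdm(complete, cfg, rng)
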