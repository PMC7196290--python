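import numpy as np
import pandas as pd
import pytest

from ctctools import CtMatrix, SyntheticCohortConfig


@pytest.fixture
def small_ct() -> CtMatrix:
    """4 genes x 3 cells with one dropout and one low-quality entry."""
    ct = pd.DataFrame(
        {
            "c1": [20.0, 25.0, 28.0, 999.0],
            "c2": [20.5, 28.0, 999.0, 24.0],
            "c3": [19.5, 26.0, 27.0, 23.0],
        },
        index=["GAPDH", "EPCAM", "VIM", "CD44"],
    )
    quality = pd.DataFrame(
        1.0, index=ct.index, columns=ct.columns
    )
    quality.loc["CD44", "c3"] = 0.4  # below the 0.65 threshold
    return CtMatrix(ct, quality)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config() -> SyntheticCohortConfig:
    """Small, fast synthetic config used across generator tests."""
    return SyntheticCohortConfig(cells_per_group=10, n_patients=20, seed=7)
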