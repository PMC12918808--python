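import numpy as np
import pandas as pd
import pytest

from frepscreen import ReadLayout, SimConfig, simulate_guide_library, simulate_screen


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate_guide_library(small_config)


@pytest.fixture(scope="session")
def small_screen(small_config, small_library):
    return simulate_screen(small_library, small_config)


@pytest.fixture(scope="session")
def layout() -> ReadLayout:
    return ReadLayout()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture()
def tiny_library_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": ["AAAAAAAAAAAA", "CCCCCCCCCCCC", "GGGGGGGGGGGG"],
            "guide_id": ["g1", "g1", "g2"],
            "gene": ["YFG1", "YFG1", "YFG2"],
            "is_control": [False, False, True],
        }
    )
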