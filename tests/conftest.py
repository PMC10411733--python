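import numpy as np
import pandas as pd
import pytest

from neobench.io import load_published_benchmark
from neobench.simulate import SimulationConfig, simulate_database


@pytest.fixture(scope="session")
def published_table() -> pd.DataFrame:
    """The shipped 16-row published benchmark table (metrics + printed ranks)."""
    return load_published_benchmark()


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def synthetic_db(default_cfg):
    return simulate_database(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
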