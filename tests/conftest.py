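import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from soildriver import SimulationConfig, generate_dataset
from soildriver.prep import PesticideCatalog


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_sites=200, n_pesticides=8, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_dataset) -> PesticideCatalog:
    return PesticideCatalog.default_for(small_dataset.concentrations.columns, rng=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def glm_frame(rng, n=300, k=4, beta=None, b0=4.5, noise=5.0):
    """Frame with standardized predictors x1..xk and y = exp(b0 + x beta) + eps."""
    x = rng.standard_normal((n, k))
    beta = np.zeros(k) if beta is None else np.asarray(beta, float)
    eta = b0 + x @ beta
    y = np.exp(eta) + rng.normal(0, noise, n)
    df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(k)])
    df["y"] = y
    return df
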