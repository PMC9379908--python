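import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from splitfert.column import GridConfig, ModelConfig
from splitfert.optimize import TimingGrid
from splitfert.precip import extract_season
from splitfert.weather import generate_record, historic_like


@pytest.fixture(scope="session")
def historic_record():
    """30 synthetic historic-like seasons (deterministic)."""
    return generate_record(historic_like(n_years=30, seed=123))


@pytest.fixture(scope="session")
def one_season(historic_record):
    return extract_season(historic_record, 1950)


@pytest.fixture(scope="session")
def default_model():
    return ModelConfig()


@pytest.fixture
def tiny_grid():
    """Three-pair timing grid for fast optimizer plumbing tests."""
    return TimingGrid(resolution=35.0, t_max=70.0)
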