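import numpy as np
import pytest

from veld.climate import ClimateConfig, generate_grid
from veld.experiments import ExperimentConfig, run_factorial


@pytest.fixture(scope="session")
def default_grid():
    """Default-resolution synthetic climatology, fixed seed."""
    return generate_grid(seed=42)


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse (5 degree) grid config for fast simulation tests."""
    return ClimateConfig(resolution=5.0, seed=7)


@pytest.fixture(scope="session")
def coarse_factorial(coarse_config):
    """Small but complete CO2 x fire x variant factorial (25 cells)."""
    cfg = ExperimentConfig(spinup_years=150, run_years=20, seed=7)
    return cfg, run_factorial(cfg, climate_config=coarse_config)
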