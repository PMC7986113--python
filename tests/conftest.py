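import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from soilncycle.climate import TemperatureSeries
from soilncycle.synth import ExperimentConfig, generate_experiment

warnings.filterwarnings("ignore", category=FutureWarning)


def noiseless_config() -> ExperimentConfig:
    """Default study configuration with every noise source switched off."""
    cfg = ExperimentConfig()
    cfg.tracer_noise_sd = 0.0
    cfg.dilution["noise_sd"] = 0.0
    cfg.assay_constants["plate_noise_rel"] = 0.0
    for spec in cfg.responses.values():
        spec["block_sd"] = 0.0
        spec["resid_sd"] = 0.0
    for regime in cfg.thermal.values():
        regime["noise_sd"] = 0.0
    return cfg


@pytest.fixture(scope="session")
def noiseless_experiment():
    return generate_experiment(noiseless_config(), seed=42)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(ExperimentConfig(), seed=7)


def make_series(temps, start="2017-01-01", freq="30min", plot_id="t"):
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start=start, periods=len(temps), freq=freq)
    return TemperatureSeries(plot_id, pd.Series(temps, index=idx))
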