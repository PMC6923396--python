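import numpy as np
import pytest

from ubafit import SimulationConfig, simulate_dilution, simulate_titration

# Table-style reference values used across tests: variant -> (KD_dimer µM, dG kJ/mol, KD_complex µM)
VARIANT_TABLE = {
    "WT": (6.8, -29.5, 40.0),
    "K420Q": (41.2, -25.0, 34.3),
    "K435Q": (15.5, -27.4, 30.4),
    "2KQ": (106.3, -22.7, 33.8),
}


@pytest.fixture
def noiseless_config():
    return SimulationConfig(
        volume_noise_cv=0.0, shift_noise_sd=0.0, intensity_noise_cv=0.0
    )


@pytest.fixture
def wt_dilution(noiseless_config):
    return simulate_dilution(noiseless_config)


@pytest.fixture
def wt_titration(noiseless_config):
    return simulate_titration(noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
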