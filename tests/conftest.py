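import numpy as np
import pytest

from nmrmeat.panel import default_panel
from nmrmeat.simdesign import AcquisitionSettings, generate_design, simulate_concentrations


@pytest.fixture(scope="session")
def default_design():
    return generate_design(8, 7, [0, 7, 14, 21, 28], 4, seed=42)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def conc_table(default_design, panel):
    return simulate_concentrations(default_design, panel, seed=42)


@pytest.fixture(scope="session")
def noiseless_panel():
    """Deterministic panel: every SD and random-effect scale zeroed."""
    p = default_panel(0.0, 0.0, 0.0, 0.0)
    for m in p:
        m.within_sd_day0 = 0.0
        m.within_sd_day28 = 0.0
    return p


@pytest.fixture
def quiet_acq():
    return AcquisitionSettings(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
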