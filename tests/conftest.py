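import numpy as np
import pytest

from pirtlab import (
    MaintenanceProfile,
    MixingVesselFeed,
    PirtParameters,
    ReactorConfig,
    chemostat_steady_state,
)


@pytest.fixture(scope="session")
def reactor():
    """Retentostat bioreactor: 1.4 L working volume, 35 mL/h feed (D = 0.025/h)."""
    return ReactorConfig(V=1.4, phi_V=0.035)


@pytest.fixture(scope="session")
def feed():
    """Mixing-vessel feed: 1.2 L, 10 g/L chemostat -> 5 g/L retentostat reservoir."""
    return MixingVesselFeed(V_S=1.2, phi_V=0.035, C_S_MC=10.0, C_S_MR=5.0)


@pytest.fixture(scope="session")
def chemostat_params():
    """Pirt parameters estimated at fast growth (chemostat regression)."""
    return PirtParameters(m_S=0.0100, Y_max=0.584)


@pytest.fixture(scope="session")
def retentostat_params():
    """Pirt parameters with the near-zero-growth maintenance plateau."""
    return PirtParameters(m_S=0.0031, Y_max=0.584)


@pytest.fixture(scope="session")
def maintenance_profile():
    return MaintenanceProfile(m_S_high=0.0100, m_S_low=0.0031, mu_mid=0.045, steepness=200.0)


@pytest.fixture(scope="session")
def C_X0(chemostat_params):
    """Biomass at the retentostat switch: chemostat steady state at D = 0.025/h."""
    return chemostat_steady_state(0.025, 10.0, chemostat_params).C_X


@pytest.fixture(scope="session")
def t_grid():
    return np.linspace(0.0, 600.0, 601)
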