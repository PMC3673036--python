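import numpy as np
import pytest

from charkit import (ChemParams2, ChemParams3, DenaturationCurve, MeltCurve,
                     ThermalParams, thermal_model, three_state_model,
                     two_state_model)

TEMP_GRID = np.arange(20.0, 81.0, 1.0)
GDN_GRID = np.round(np.arange(0.0, 6.05, 0.1), 10)


@pytest.fixture(scope="session")
def temp_grid():
    return TEMP_GRID.copy()


@pytest.fixture(scope="session")
def gdn_grid():
    return GDN_GRID.copy()


@pytest.fixture
def ephb1_thermal_params():
    """EphB1 melt truth: Tm 59.7 °C, ΔHm 156.6 kJ/mol, flat 1→0 baselines."""
    return ThermalParams(tm=59.7, dhm=156.6, a_n=1.0, b_n=0.0, a_u=0.0, b_u=0.0)


@pytest.fixture
def clean_melt(ephb1_thermal_params, temp_grid):
    return MeltCurve(temp_grid, thermal_model(temp_grid, ephb1_thermal_params),
                     sample_id="EphB1")


@pytest.fixture
def two_state_params():
    return ChemParams2(dg_h2o=20.0, m_value=10.0, a_n=1.0, b_n=-0.01,
                       a_u=0.1, b_u=0.0)


@pytest.fixture
def three_state_params():
    """Well-separated intermediate (Cm1 1.25 M, Cm2 3.5 M, half amplitude)."""
    return ChemParams3(dg1=15.0, m1=12.0, dg2=35.0, m2=10.0,
                       a_n=1.0, b_n=-0.01, a_u=0.1, b_u=0.0, z_i=0.5)


@pytest.fixture
def clean_two_state(two_state_params, gdn_grid):
    return DenaturationCurve(gdn_grid, two_state_model(gdn_grid, two_state_params))


@pytest.fixture
def clean_three_state(three_state_params, gdn_grid):
    return DenaturationCurve(gdn_grid, three_state_model(gdn_grid, three_state_params))
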