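import numpy as np
import pytest
from hypothesis import settings

from myooef import (
    AcquisitionProtocol,
    AlphaTable,
    SimulationConfig,
    TissueState,
    simulate_session,
    voxel_signal,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return AlphaTable.default()


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol.t2prep_default()


@pytest.fixture(scope="session")
def rest_state():
    return TissueState(oef=0.73, mbv=0.06, r20t=24.5, r21t=1.06e5)


@pytest.fixture(scope="session")
def stress_state():
    return TissueState(oef=0.37, mbv=0.10, r20t=24.5, r21t=1.06e5)


@pytest.fixture(scope="session")
def myo_rest_clean(rest_state, protocol, table):
    return voxel_signal(rest_state, protocol, 1000.0, table)


@pytest.fixture(scope="session")
def myo_stress_clean(stress_state, protocol, table):
    return voxel_signal(stress_state, protocol, 1000.0, table, condition="stress")


@pytest.fixture(scope="session")
def clean_session():
    return simulate_session(SimulationConfig())
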