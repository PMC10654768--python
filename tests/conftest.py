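"""Shared fixtures: the expensive reference trajectories are built once."""

import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("default", derandomize=True, deadline=None)
hypothesis_settings.load_profile("default")

from astroca import (
    CircuitParams,
    LHParams,
    SystemState,
    simulate,
    simulate_circuit,
)


@pytest.fixture(scope="session")
def lh_params():
    return LHParams()


@pytest.fixture(scope="session")
def lh_traj(lh_params):
    """Reference-model run at default parameters, long enough for >= 5 cycles."""
    return simulate(lh_params, t_end=2000.0, dt_out=0.5)


@pytest.fixture(scope="session")
def lh_traj_alt_init(lh_params):
    """Same system started elsewhere in the basin of the limit cycle."""
    return simulate(lh_params, init=SystemState(0.3, 1.0, 0.2), t_end=2000.0, dt_out=0.5)


@pytest.fixture(scope="session")
def circuit_cp(lh_params):
    return CircuitParams.calibrated(lh_params)


@pytest.fixture(scope="session")
def circuit_traj(circuit_cp):
    return simulate_circuit(circuit_cp, t_end=2000.0, dt_out=0.5)
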