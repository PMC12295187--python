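import numpy as np
import pytest

from lr1spiral import ModelParams, resting_state
from lr1spiral.kernels import CellKernel


@pytest.fixture(scope="session")
def control_params():
    return ModelParams()


@pytest.fixture(scope="session")
def rest_control(control_params):
    """Quiescent rest state of the control parameter set (session-cached:
    every gate at its steady state, |dV/dt| below tolerance)."""
    return resting_state(control_params)


@pytest.fixture(scope="session")
def prepaced_control(control_params):
    """Control state after a convergence-checked 50-beat train at PCL 500."""
    from lr1spiral import PacingProtocol, prepace_cell

    return prepace_cell(control_params, PacingProtocol(500.0, 50))


@pytest.fixture(scope="session")
def control_kernel(control_params):
    return CellKernel(control_params, dt=0.01)


@pytest.fixture(scope="session")
def control_ap(rest_control, control_kernel):
    """One AP from rest: (t, V) at 0.05 ms sampling over a 500 ms window."""
    t, v, _ = control_kernel.run_trace(
        rest_control.as_array(), 500.0, stim_starts=[0.0],
        stim_duration=1.0, stim_amplitude=57.0, record_dt=0.05)
    return t, v
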