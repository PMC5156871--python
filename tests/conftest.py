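import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spherocycle.io_cli import (
    MONOLAYER_INITIAL,
    MONOLAYER_RATES,
    OBSERVED_VOLUMES,
    SPHEROID_INITIAL,
    SPHEROID_PARAMS,
    CALIBRATION_OBSERVABLES,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def printed_rates():
    """The 2-dp printed cycle rates used by the downstream simulations."""
    return MONOLAYER_RATES


@pytest.fixture(scope="session")
def calibration_observables():
    return CALIBRATION_OBSERVABLES


@pytest.fixture(scope="session")
def mono_init():
    return MONOLAYER_INITIAL


@pytest.fixture(scope="session")
def spheroid_params():
    return SPHEROID_PARAMS


@pytest.fixture(scope="session")
def spheroid_init():
    return SPHEROID_INITIAL


@pytest.fixture(scope="session")
def observed_volumes():
    return OBSERVED_VOLUMES


@pytest.fixture(scope="session")
def control_equilibrium(spheroid_params, spheroid_init):
    """Control spheroid steady state, solved once per session."""
    from spherocycle import simulate

    guess = simulate.equilibrium_by_integration(spheroid_params, spheroid_init)
    return simulate.solve_equilibrium(spheroid_params, guess=guess)
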