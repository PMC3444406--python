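import numpy as np
import pytest

from diffcea import (
    DiffusionDrivers,
    EconomicSettings,
    default_trajectory,
    generate_default,
)
from diffcea.health_model import N_STATES, HealthState, TransitionMatrix


@pytest.fixture(scope="session")
def settings():
    return EconomicSettings()


@pytest.fixture(scope="session")
def params():
    return generate_default()


@pytest.fixture(scope="session")
def trajectory():
    return default_trajectory()


@pytest.fixture(scope="session")
def drivers_by_year(trajectory):
    return {p.year: p for p in trajectory}


@pytest.fixture(scope="session")
def calibrated(drivers_by_year):
    """Parameter set calibrated to the combined-2010 incremental outcomes
    (dE = 0.0728 QALY, dC = EUR 1,630 at drivers failure 0.20, total
    non-compliance 0.26, uptake 0.50), shared across test modules."""
    from diffcea.synthetic_params import CalibrationTarget, calibrate

    targets = [
        CalibrationTarget("delta_effects", 0.0728, drivers_by_year["2010"], rel_tol=0.02),
        CalibrationTarget("delta_costs", 1630.0, drivers_by_year["2010"], rel_tol=0.02),
    ]
    ps, report = calibrate(generate_default(), targets)
    return ps, report


def random_stochastic_matrix(rng: np.random.Generator) -> TransitionMatrix:
    """Random valid transition matrix: Dirichlet rows, absorbing death,
    no transitions back out of relapse/metastasis into disease-free."""
    p = np.zeros((N_STATES, N_STATES))
    p[0] = rng.dirichlet(np.ones(N_STATES))
    p[1, 1:] = rng.dirichlet(np.ones(3))
    p[2, 2:] = rng.dirichlet(np.ones(2))
    p[3, HealthState.DEAD] = 1.0
    return TransitionMatrix(p)
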