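import numpy as np
import pytest

from fhm_hpg.parameters import ModelParameters, Physiology
from fhm_hpg.simulate import SolverOptions, initialize_baseline


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def phys():
    return Physiology()


@pytest.fixture(scope="session")
def coarse_solver():
    return SolverOptions(rtol=1e-6, atol=1e-10, baseline_tol=1e-5)


@pytest.fixture(scope="session")
def tight_solver():
    return SolverOptions(rtol=1e-10, atol=1e-14, baseline_tol=1e-8,
                         baseline_horizon=8000)


@pytest.fixture(scope="session")
def baseline(phys, params, coarse_solver):
    """Coarse-tolerance periodic baseline, shared across tests."""
    return initialize_baseline(phys, params, coarse_solver)


@pytest.fixture(scope="session")
def tight_baseline(phys, params, tight_solver):
    return initialize_baseline(phys, params, tight_solver)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
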