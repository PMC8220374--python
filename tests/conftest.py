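import numpy as np
import pytest

from bobkit.bob import OptimizationSettings
from bobkit.lip import LipParams
from bobkit.models import (
    ContactMode,
    StanceSpec,
    dof4_model,
    dof5_model,
    lip_model,
    reference_anthropometrics,
    toy_pendulum_flywheel,
)


@pytest.fixture(scope="session")
def ref_params():
    return reference_anthropometrics()


@pytest.fixture(scope="session")
def lip_ref():
    """LIP with the reference foot length and standing COM height."""
    return lip_model(fl=0.23, ybar=1.12)


@pytest.fixture(scope="session")
def lip_params_ref():
    return LipParams(fl=0.23, ybar=1.12)


@pytest.fixture(scope="session")
def lip_unit():
    """Nondimensional LIP: fl = 1 and ybar chosen so omega = 1."""
    return lip_model(fl=1.0, ybar=9.81)


@pytest.fixture(scope="session")
def m4(ref_params):
    return dof4_model(ref_params)


@pytest.fixture(scope="session")
def m5(ref_params):
    return dof5_model(ref_params)


@pytest.fixture(scope="session")
def toy():
    return toy_pendulum_flywheel()


@pytest.fixture(scope="session")
def stance5():
    return StanceSpec((0.0, 0.23), frozenset(
        {ContactMode.FLAT, ContactMode.HEEL_PIVOT, ContactMode.TOE_PIVOT}))


@pytest.fixture(scope="session")
def quick_settings():
    """Small-but-converged optimizer settings for unit tests."""
    return OptimizationSettings(horizon=2.0, n_nodes=16, seed=1,
                                n_multistarts=1, max_iter=150)


@pytest.fixture(scope="session")
def lip_settings():
    return OptimizationSettings(horizon=4.0, n_nodes=30, seed=1, n_multistarts=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
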