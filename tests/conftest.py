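import numpy as np
import pytest

from devsens import dynamics as dyn
from devsens import sensitivity as sens


@pytest.fixture(scope="session")
def toggle():
    return dyn.toggle_switch()


@pytest.fixture(scope="session")
def toggle_env():
    return dyn.toggle_switch(include_env=True)


@pytest.fixture(scope="session")
def grid50():
    return dyn.TimeGrid(0.0, 50.0, 1.0)


@pytest.fixture(scope="session")
def sens_toggle(toggle, grid50):
    """Variational sensitivities of the two-parameter switch at lam* = 0."""
    return sens.sensitivities_variational(toggle, np.zeros(2), np.zeros(2), grid50)


@pytest.fixture(scope="session")
def sens_env(toggle_env, grid50):
    """Variational sensitivities of the environmentally extended switch."""
    return sens.sensitivities_variational(toggle_env, np.zeros(2), np.zeros(3), grid50)


@pytest.fixture(scope="session")
def linear_relax():
    """1-D relaxation dx/dt = lam - x: s(t) = 1 - exp(-t) in closed form."""
    return dyn.ODESystem(
        n_states=1,
        n_params=1,
        rhs=lambda t, x, lam: np.array([lam[0] - x[0]]),
        jac_x=lambda t, x, lam: np.array([[-1.0]]),
        jac_lambda=lambda t, x, lam: np.array([[1.0]]),
        name="linear_relax",
    )
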