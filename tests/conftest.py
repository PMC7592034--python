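import numpy as np
import pytest
from scipy.optimize import brentq

from delayepi import (
    EpidemicParams,
    integrate_nrde,
    integrate_seir,
    recover_compartments,
)


@pytest.fixture(scope="session")
def comparison_params():
    """The headline comparison conditions: R0 = 2.5, tau_i = 1.0, s0 = 0.995."""
    return EpidemicParams(r0=2.5, tau_i=1.0, s0=0.995, epsilon=0.0005)


@pytest.fixture(scope="session")
def nrde_run(comparison_params):
    """One converged two-delay run at the comparison conditions (h = 0.01)."""
    traj = integrate_nrde(comparison_params, horizon=60.0, step=0.01)
    return traj, recover_compartments(traj)


@pytest.fixture(scope="session")
def seir_run(comparison_params):
    return integrate_seir(comparison_params, horizon=60.0, step=0.01)


def final_size_root(r0: float, s0: float) -> float:
    """Independent oracle: r_inf = 1 - s_inf with s_inf the root of the
    classical final-size relation s_inf = s0 * exp(-R0 * (1 - s_inf))."""
    s_inf = brentq(lambda s: s - s0 * np.exp(-r0 * (1.0 - s)), 1e-14, 1.0 - 1e-14)
    return 1.0 - s_inf
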