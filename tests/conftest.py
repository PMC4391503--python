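import numpy as np
import pytest
from scipy.linalg import solve_banded

from mossbranch import ScenarioParams, get_scenario, simulate_dataset


@pytest.fixture(scope="session")
def wt_scenario():
    return get_scenario("wild_type")


@pytest.fixture(scope="session")
def wt_dataset(wt_scenario):
    """A 60-gametophore wild-type dataset shared across tests."""
    return simulate_dataset(wt_scenario, n=60, seed=1)


def make_scenario(**kwargs) -> ScenarioParams:
    """A small hand-set scenario for unit tests of single operations."""
    defaults = dict(
        name="test",
        H_apex_mu=80.0,
        H_apex_sigma=0.0,
        H_mu=20.0,
        H_sigma=0.0,
        T_mu=3.0,
        T_sigma=0.0,
        v=0.01,
        K_A=0.05,
        K_B=0.05,
        dt=0.005,
        basal_zone_depth=0,
        basal_T_factor=1.0,
        growth_delay_max=0,
        total_steps=100,
        length_range=(1, 1000),
    )
    defaults.update(kwargs)
    return ScenarioParams(**defaults)


def steady_state_oracle(scenario, H_apex, H, is_branch):
    """Direct tridiagonal solve of the no-growth steady state.

    Independent of the time-stepper: builds the linear balance
    K_B(c_{i+1}-c_i) + K_A(c_{i-1}-c_i) [+ K_B(H-c_i) if branch] - v c_i = 0
    with the apex clamped at H_apex above the top metamer and a no-flux
    mirror below the bottom one, and solves it with a banded solver.
    """
    n = len(is_branch)
    KA, KB, v = scenario.K_A, scenario.K_B, scenario.v
    diag = np.full(n, KA + KB + v)
    diag[0] -= KA  # basal mirror: the K_A exchange with "c_0" cancels
    rhs = np.zeros(n)
    rhs[-1] += KB * H_apex
    for i in range(n):
        if is_branch[i]:
            diag[i] += KB
            rhs[i] += KB * H
    ab = np.zeros((3, n))
    ab[0, 1:] = -KB  # super-diagonal: coupling to the metamer above
    ab[1, :] = diag
    ab[2, :-1] = -KA  # sub-diagonal: coupling to the metamer below
    return solve_banded((1, 1), ab, rhs)
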