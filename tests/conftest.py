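"""Shared fixtures: the published parameter set, the solved resting state and
one session-scoped trajectory per scenario (the expensive simulations are run
once and shared by the behavioural and acceptance tests)."""

import numpy as np
import pytest
from hypothesis import settings

import ngvsim as ngv

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> ngv.ParameterSet:
    return ngv.ParameterSet()


@pytest.fixture(scope="session")
def steady(params):
    return ngv.find_steady_state(params)


@pytest.fixture(scope="session")
def invitro_traj(params, steady):
    scenario = ngv.make_scenario("in_vitro")
    return ngv.integrate(scenario, params, y0=steady.state)


@pytest.fixture(scope="session")
def rodent_traj(params, steady):
    scenario = ngv.make_scenario("in_vivo_rodent")
    return ngv.integrate(scenario, params, y0=steady.state)


@pytest.fixture(scope="session")
def human_traj(params, steady):
    scenario = ngv.make_scenario("in_vivo_human")
    return ngv.integrate(scenario, params, y0=steady.state)


def random_valid_states(params, n, seed=0):
    """Random states satisfying the state invariants, spread around rest."""
    rng = np.random.default_rng(seed)
    rest = ngv.resting_state()
    ix = ngv.STATE_INDEX
    states = []
    for _ in range(n):
        y = rest * rng.uniform(0.85, 1.15, rest.shape)
        y[ix["psi_n"]] = rng.uniform(-85.0, 20.0)
        for name in ("ATP_n", "ATP_g"):
            y[ix[name]] = min(y[ix[name]], 0.999 * params.a_tot)
        for name in ("NADH_cyto_n", "NADH_cyto_g", "NADH_mito_n", "NADH_mito_g"):
            y[ix[name]] = np.clip(y[ix[name]], 1e-4, 0.999 * params.n_tot)
        for name in ("PCr_n", "PCr_g"):
            y[ix[name]] = np.clip(y[ix[name]], 0.01, 0.99 * params.c_tot)
        y[ix["h"]] = rng.uniform(0.0, 1.0)
        y[ix["n_gate"]] = rng.uniform(0.0, 1.0)
        y[ix["O2_c"]] = rng.uniform(4.0, 0.95 * params.hb_op)
        states.append(y)
    return states
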