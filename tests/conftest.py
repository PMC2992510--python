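import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import root

from ferrisim import (
    ModelParameters,
    SystemState,
    make_parameters,
    run_to_steady_state,
    state_for_ratio,
    total_ferritin,
    total_iron,
)
from ferrisim.model import _iron_weights, _jacobian, _rhs, k_loss_vector

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The published default parameter set (N = 50)."""
    return make_parameters()


@pytest.fixture(scope="session")
def small_params() -> ModelParameters:
    """Coarse lumping (N = 10) for fast structural/oracle tests."""
    return make_parameters(atoms_per_package=250)


@pytest.fixture(scope="session")
def base_1000(params) -> "SteadyStateResult":
    """Steady state at the reference 1000:1 iron:ferritin condition."""
    return run_to_steady_state(state_for_ratio(1000.0, params), params)


def random_state(params: ModelParameters, seed: int, scale: float = 1e-6) -> SystemState:
    """A strictly positive random state for property tests."""
    rng = np.random.default_rng(seed)
    n = params.n_packages
    return SystemState(
        fe=float(rng.uniform(0.1, 1.0) * scale),
        fn=rng.uniform(0.1, 1.0, n + 1) * scale,
        c=rng.uniform(0.1, 1.0, n + 1) * scale,
    )


def algebraic_steady_state(
    params: ModelParameters, reference: SystemState, perturb: float = 1e-3, seed: int = 1
) -> np.ndarray:
    """Independent steady-state oracle: solve the rate equations as an
    algebraic root problem with the two conservation laws imposed in place
    of the (redundant) iron and Fn_0 balances, starting from a perturbed
    guess near ``reference``.
    """
    kloss = k_loss_vector(params)
    target_iron = total_iron(reference)
    target_fn = total_ferritin(reference)
    weights = _iron_weights(params.n_packages)

    def fun(y):
        r = _rhs(y, params, kloss)
        r[0] = weights @ y - target_iron
        r[1] = y[1:].sum() - target_fn
        return r

    def jac(y):
        J = _jacobian(y, params, kloss)
        J[0] = weights
        J[1] = np.concatenate(([0.0], np.ones(len(y) - 1)))
        return J

    rng = np.random.default_rng(seed)
    y0 = reference.to_vector() * (1.0 + perturb * rng.uniform(-1, 1, 2 * params.n_packages + 3))
    sol = root(fun, y0, jac=jac, method="hybr")
    assert sol.success, sol.message
    return sol.x
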