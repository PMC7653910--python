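import pytest
from hypothesis import HealthCheck, settings

from seirtime import integrate_seir, integrate_sir, make_parameters

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def sir_params():
    """The illustration parameters: R0=2, gamma=0.5/d, I0=1e-4, SIR limit."""
    return make_parameters(2.0, 0.5, None, 1e-4)


@pytest.fixture(scope="session")
def seir_params():
    """SEIR with equal incubation and infectious periods of 2 days."""
    return make_parameters(2.0, 0.5, 0.5, 1e-4)


@pytest.fixture(scope="session")
def sir_ode(sir_params):
    return integrate_sir(sir_params)


@pytest.fixture(scope="session")
def seir_ode(seir_params):
    return integrate_seir(seir_params)
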