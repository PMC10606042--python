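import numpy as np
import pytest

from siqrs import (
    BASE_RATES,
    DegreeState,
    ModelParameters,
    truncated_power_law,
)


@pytest.fixture(scope="session")
def dist5():
    return truncated_power_law(3.0, 5)


@pytest.fixture(scope="session")
def dist50():
    return truncated_power_law(3.0, 50)


@pytest.fixture(scope="session")
def make_params():
    """Base rate set with the transmission/control knobs supplied per test."""

    def _make(beta, p=0.0, gamma=1.0, delta=0.0, **overrides):
        rates = {**BASE_RATES, **overrides}
        return ModelParameters(beta=beta, p=p, gamma=gamma, delta=delta, **rates)

    return _make


@pytest.fixture(scope="session")
def endemic_params(make_params):
    """Well above threshold on the k^-3 network (R0 ~ 6.6 at M=50)."""
    return make_params(beta=0.4, p=0.3, gamma=0.5, delta=0.1)


@pytest.fixture(scope="session")
def subcritical_params(make_params):
    """Well below threshold (R0 ~ 0.33 at M=50)."""
    return make_params(beta=0.02, p=0.3, gamma=0.5, delta=0.1)


@pytest.fixture()
def random_interior_state():
    """Random valid per-degree states strictly inside the invariant region."""

    def _draw(params, n_degrees, rng, fill_low=0.2, fill_high=0.95):
        bound = params.dfe_susceptible_level
        raw = rng.uniform(0.01, 1.0, size=(4, n_degrees))
        raw *= rng.uniform(fill_low, fill_high) * bound / raw.sum(axis=0, keepdims=True)
        return DegreeState(S=raw[0], I=raw[1], Q=raw[2], R=raw[3])

    return _draw
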