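import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from siqrs import (
    DegreeState,
    ModelParameters,
    aggregate,
    check_invariant_region,
    integrate,
    rhs,
    solve_endemic,
    theta,
    truncated_power_law,
)


class TestParameters:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(b=-0.1, d=0.01, r=0.02, beta=0.1, p=0.1, gamma=0.5,
                            delta=0.1, lam=0.02, eta=0.3, mu=0.7)

    def test_alertness_probability_bounded(self):
        with pytest.raises(ValueError):
            ModelParameters(b=0.4, d=0.01, r=0.02, beta=0.1, p=1.5, gamma=0.5,
                            delta=0.1, lam=0.02, eta=0.3, mu=0.7)

    def test_r_below_natural_death_warns(self):
        with pytest.warns(UserWarning):
            ModelParameters(b=0.4, d=0.05, r=0.01, beta=0.1, p=0.1, gamma=0.5,
                            delta=0.1, lam=0.02, eta=0.3, mu=0.7)

    def test_effective_rate_tracks_replacement(self, make_params):
        params = make_params(beta=0.2, p=0.5, gamma=0.5)
        assert params.beta_eff == pytest.approx(0.75 * 0.2)
        # recomputed on access, never stale
        assert params.replace(p=0.0).beta_eff == pytest.approx(0.2)


class TestTheta:
    def test_no_infection_gives_zero(self, dist5, make_params):
        state = DegreeState.uniform_seed(make_params(beta=0.1), 5, i0=0.0)
        assert theta(state, dist5) == 0.0

    def test_uniform_infection_is_identity(self, dist50):
        # edge weights k p(k)/<k> sum to 1, so constant I_k = c maps to c
        m = dist50.degrees.size
        state = DegreeState(S=np.zeros(m), I=np.full(m, 0.37), Q=np.zeros(m), R=np.zeros(m))
        assert theta(state, dist50) == pytest.approx(0.37, rel=1e-12)

    def test_two_degree_hand_expansion(self):
        dist = truncated_power_law(3.0, 2)
        p1, p2 = dist.probabilities
        state = DegreeState(S=np.zeros(2), I=np.array([0.1, 0.3]), Q=np.zeros(2), R=np.zeros(2))
        expected = (1 * p1 * 0.1 + 2 * p2 * 0.3) / (1 * p1 + 2 * p2)
        assert theta(state, dist) == pytest.approx(expected, rel=1e-14)

    def test_dimension_mismatch_rejected(self, dist5):
        state = DegreeState.uniform_seed(
            ModelParameters(b=0.4, d=0.01, r=0.02, beta=0.1, p=0.0, gamma=1.0,
                            delta=0.0, lam=0.02, eta=0.3, mu=0.7), 7)
        with pytest.raises(ValueError):
            theta(state, dist5)


class TestRhs:
    def test_vanishes_at_disease_free_state(self, dist50, endemic_params):
        m = dist50.degrees.size
        s0 = endemic_params.dfe_susceptible_level
        state = DegreeState(S=np.full(m, s0), I=np.zeros(m), Q=np.zeros(m), R=np.zeros(m))
        deriv = rhs(state, endemic_params, dist50)
        assert np.max(np.abs(deriv.to_vector())) < 1e-14

    def test_no_transmission_pure_decay(self, dist5, make_params):
        params = make_params(beta=0.0, delta=0.1)
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.0, 0.2, size=(4, 5))
        state = DegreeState(*raw)
        deriv = rhs(state, params, dist5)
        np.testing.assert_allclose(
            deriv.I, -params.infectious_exit_rate * state.I, rtol=1e-14
        )

    def test_vanishes_at_endemic_fixed_point(self, dist50, endemic_params):
        eq = solve_endemic(endemic_params, dist50)
        deriv = rhs(eq.state, endemic_params, dist50)
        assert np.max(np.abs(deriv.to_vector())) < 1e-9

    def test_infection_free_subsystem_fixed(self, dist5, endemic_params):
        # I = Q = R = 0 is invariant regardless of S
        state = DegreeState(S=np.linspace(0.1, 0.9, 5), I=np.zeros(5), Q=np.zeros(5), R=np.zeros(5))
        deriv = rhs(state, endemic_params, dist5)
        assert np.all(deriv.I == 0) and np.all(deriv.Q == 0) and np.all(deriv.R == 0)

    def test_cross_degree_coupling_only_through_theta(self, dist5, endemic_params):
        """Perturbing I_j moves dS_k, dI_k (k != j) only via the theta term."""
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.01, 0.2, size=(4, 5))
        state = DegreeState(*raw)
        base = rhs(state, endemic_params, dist5)
        j, eps = 2, 1e-7
        bumped = state.copy()
        bumped.I[j] += eps
        pert = rhs(bumped, endemic_params, dist5)
        gj = dist5.edge_weights()[j]
        k = dist5.degrees.astype(float)
        expected_dS = -endemic_params.beta_eff * k * state.S * gj * eps
        expected_dI = endemic_params.beta_eff * k * state.S * gj * eps
        mask = np.arange(5) != j
        np.testing.assert_allclose(
            (pert.S - base.S)[mask], expected_dS[mask], rtol=1e-6
        )
        np.testing.assert_allclose(
            (pert.I - base.I)[mask], expected_dI[mask], rtol=1e-6
        )
        # Q and R rows are strictly degree-local
        assert np.all((pert.Q - base.Q)[mask] == 0)
        assert np.all((pert.R - base.R)[mask] == 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_total_mass_differential_inequality(self, seed, dist5, endemic_params):
        """d(S+I+Q+R)/dt <= b - (b+d)(S+I+Q+R) pointwise at valid states."""
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.0, 1.0, size=(4, 5))
        raw /= np.maximum(raw.sum(axis=0, keepdims=True), 1.0)
        state = DegreeState(*raw)
        deriv = rhs(state, endemic_params, dist5)
        total = state.total
        dtotal = deriv.S + deriv.I + deriv.Q + deriv.R
        bound = endemic_params.b - (endemic_params.b + endemic_params.d) * total
        assert np.all(dtotal <= bound + 1e-12)

    def test_nan_state_rejected(self, dist5, endemic_params):
        state = DegreeState(S=np.full(5, np.nan), I=np.zeros(5), Q=np.zeros(5), R=np.zeros(5))
        with pytest.raises(ValueError):
            rhs(state, endemic_params, dist5)


class TestIntegrate:
    def test_disease_free_start_stays_constant(self, dist5, endemic_params):
        init = DegreeState.uniform_seed(endemic_params, 5, i0=0.0)
        traj = integrate(endemic_params, dist5, init, 50.0, n_report=11)
        np.testing.assert_allclose(traj.y, np.tile(init.to_vector(), (11, 1)), atol=1e-8)

    def test_subthreshold_infection_dies_out(self, dist50, subcritical_params):
        init = DegreeState.uniform_seed(subcritical_params, 50, i0=0.01)
        traj = integrate(subcritical_params, dist50, init, 3000.0, n_report=31)
        agg = aggregate(traj)
        assert agg["I"].iloc[-1] < 1e-6
        assert np.all(np.diff(agg["I"].to_numpy()) <= 1e-12)

    def test_superthreshold_reaches_endemic_state(self, endemic_params):
        dist = truncated_power_law(3.0, 10)
        eq = solve_endemic(endemic_params, dist)
        init = DegreeState.uniform_seed(endemic_params, 10, i0=0.01)
        traj = integrate(endemic_params, dist, init, 2000.0, n_report=21)
        dev = np.max(np.abs(traj.final_state.to_vector() - eq.state.to_vector()))
        assert dev < 1e-6
        assert traj.converged

    def test_halved_tolerances_change_little(self, dist5, endemic_params):
        init = DegreeState.uniform_seed(endemic_params, 5, i0=0.01)
        rtol = 1e-8
        a = aggregate(integrate(endemic_params, dist5, init, 100.0, rtol=rtol, n_report=21))
        b = aggregate(integrate(endemic_params, dist5, init, 100.0, rtol=rtol / 2,
                                atol=0.5e-10, n_report=21))
        for col in ("S", "I", "Q", "R"):
            assert np.max(np.abs(a[col] - b[col])) < 10 * rtol

    def test_invalid_horizon_rejected(self, dist5, endemic_params):
        init = DegreeState.uniform_seed(endemic_params, 5)
        with pytest.raises(ValueError):
            integrate(endemic_params, dist5, init, 0.0)


class TestAggregate:
    def test_homogeneous_state_is_common_value(self, dist50, endemic_params):
        m = dist50.degrees.size
        init = DegreeState(S=np.full(m, 0.5), I=np.full(m, 0.1),
                           Q=np.full(m, 0.05), R=np.full(m, 0.2))
        traj = integrate(endemic_params, dist50, init, 1e-6, n_report=2)
        agg = aggregate(traj)
        assert agg["S"].iloc[0] == pytest.approx(0.5, rel=1e-9)
        assert agg["I"].iloc[0] == pytest.approx(0.1, rel=1e-9)

    def test_point_mass_distribution_passthrough(self, endemic_params):
        dist = truncated_power_law(3.0, 1)
        init = DegreeState(S=np.array([0.6]), I=np.array([0.2]),
                           Q=np.array([0.0]), R=np.array([0.1]))
        traj = integrate(endemic_params, dist, init, 1e-6, n_report=2)
        agg = aggregate(traj)
        assert agg["I"].iloc[0] == pytest.approx(0.2, rel=1e-9)


class TestInvariantRegion:
    def test_bound_value_from_base_rates(self, dist5, endemic_params):
        init = DegreeState.uniform_seed(endemic_params, 5, i0=0.01)
        traj = integrate(endemic_params, dist5, init, 10.0, n_report=5)
        report = check_invariant_region(traj)
        assert report.bound == pytest.approx(0.4 / 0.41, rel=1e-14)

    def test_interior_start_stays_inside(self, dist50, endemic_params, random_interior_state):
        rng = np.random.default_rng(5)
        init = random_interior_state(endemic_params, 50, rng)
        traj = integrate(endemic_params, dist50, init, 500.0, n_report=51)
        report = check_invariant_region(traj, tol=1e-6)
        assert report.within_bound_all_times
        assert not report.has_negative

    def test_start_above_bound_is_attracted_inside(self, dist5, endemic_params):
        # totals start at 0.999 > b/(b+d) = 0.9756...
        init = DegreeState(S=np.full(5, 0.799), I=np.full(5, 0.1),
                           Q=np.full(5, 0.05), R=np.full(5, 0.05))
        traj = integrate(endemic_params, dist5, init, 2000.0, n_report=41)
        report = check_invariant_region(traj, tol=1e-6)
        assert not report.within_bound_all_times  # starts outside by construction
        assert report.within_bound_tail
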