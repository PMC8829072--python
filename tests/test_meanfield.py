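import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from isvor import IsvorParams, ParameterError, StateVector, equilibria, integrate, isvor_rhs
from conftest import params_with, random_simplex

probabilities = st.floats(0.0, 1.0, allow_nan=False)
rate_sets = st.fixed_dictionaries(
    {name: probabilities for name in IsvorParams().probability_fields
     if name != "epsilon"}
).map(lambda d: IsvorParams(**d))
simplex_points = st.lists(
    st.floats(1e-3, 1.0, allow_nan=False), min_size=5, max_size=5
).map(lambda w: np.array(w) / np.sum(w))


class TestRhs:
    def test_all_ignorant_is_stationary(self, defaults):
        for variant in ("as_printed", "conserving"):
            assert np.all(isvor_rhs([1, 0, 0, 0, 0], defaults, variant) == 0)

    def test_pure_spreader_dS_hand_value(self, defaults):
        # dS = -mu1*k - (xi1 + gamma) = -0.5*10 - 0.8 at the default rates
        d = isvor_rhs([0, 1, 0, 0, 0], defaults, "as_printed")
        assert d[1] == pytest.approx(-5.8)

    def test_printed_leak_equals_theta_O_I(self, defaults):
        # at (I=0.5, O=0.5) the printed system leaks theta*O*I = 0.0625
        s = [0.5, 0.0, 0.0, 0.5, 0.0]
        assert isvor_rhs(s, defaults, "as_printed").sum() == pytest.approx(0.0625)
        assert isvor_rhs(s, defaults, "conserving").sum() == 0.0

    def test_conservation_defect_identity_on_simplex(self, defaults):
        # symbolic identity: sum of the printed RHS = theta*O*I on the simplex
        rng = np.random.default_rng(7)
        for state in random_simplex(rng, 500):
            leak = isvor_rhs(state, defaults, "as_printed").sum()
            assert leak == pytest.approx(defaults.theta * state[3] * state[0], abs=1e-12)
            assert abs(isvor_rhs(state, defaults, "conserving").sum()) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(p=rate_sets, state=simplex_points)
    def test_leak_identity_holds_for_all_rates_and_states(self, p, state):
        leak = isvor_rhs(state, p, "as_printed").sum()
        assert leak == pytest.approx(p.theta * state[3] * state[0], abs=1e-12)
        assert isvor_rhs(state, p, "conserving").sum() == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(p=rate_sets, i1=st.floats(0.0, 1.0, allow_nan=False))
    def test_rumor_free_states_stationary_for_all_rates(self, p, i1):
        state = [i1, 0.0, 0.0, 0.0, 1.0 - i1]
        assert np.all(isvor_rhs(state, p, "as_printed") == 0.0)
        assert np.all(isvor_rhs(state, p, "conserving") == 0.0)

    def test_unknown_variant_rejected(self, defaults):
        with pytest.raises(ParameterError):
            isvor_rhs([1, 0, 0, 0, 0], defaults, "leaky")  # type: ignore[arg-type]

    def test_epsilon_flag_moves_density_from_I_to_R(self):
        p = IsvorParams(epsilon=0.3)
        s = [0.5, 0.5, 0, 0, 0]
        base = isvor_rhs(s, p, "conserving")
        with_eps = isvor_rhs(s, p, "conserving", include_epsilon=True)
        shift = p.k * p.epsilon * 0.5 * 0.5
        assert with_eps[0] == pytest.approx(base[0] - shift)
        assert with_eps[4] == pytest.approx(base[4] + shift)


class TestIntegrate:
    def test_equilibrium_initial_condition_stays_put(self, defaults):
        traj = integrate(defaults, [1, 0, 0, 0, 0], t_max=50)
        assert np.allclose(traj.data, traj.data[0], atol=1e-9)

    def test_rumor_dies_out_and_recovery_plateaus(self, defaults):
        init = [1 - 1 / 2000, 1 / 2000, 0, 0, 0]
        traj = integrate(defaults, init, t_max=100, variant="conserving")
        final = traj.final()
        assert final["S"] < 1e-3 and final["V"] < 1e-3 and final["O"] < 1e-3
        # R has reached its plateau: negligible change over the last decade
        r = traj["R"]
        assert abs(r[-1] - r[int(0.9 * len(r))]) < 1e-4

    def test_conserving_trajectory_stays_on_simplex(self, defaults):
        traj = integrate(defaults, [0.9, 0.05, 0.02, 0.02, 0.01], t_max=200)
        totals = traj.data.sum(axis=1)
        assert np.all(np.abs(totals - 1) < 1e-6)
        assert traj.data.min() > -1e-9

    def test_variants_agree_when_theta_zero(self, defaults):
        p = defaults.replace(theta=0.0)
        init = [0.99, 0.01, 0, 0, 0]
        a = integrate(p, init, 50, variant="as_printed")
        b = integrate(p, init, 50, variant="conserving")
        assert np.allclose(a.data, b.data, atol=1e-6)

    def test_euler_matches_adaptive_at_small_step(self, defaults):
        init = [0.99, 0.01, 0, 0, 0]
        rk = integrate(defaults, init, 10, method="rk_adaptive", n_out=11)
        eu = integrate(defaults, init, 10, method="euler_dt", dt=1e-3)
        assert np.allclose(rk.data[-1], eu.data[-1], atol=1e-2)

    def test_reduces_to_three_compartment_flow(self):
        # with every V/O channel off, the system is the I/S/R contact flow
        p = params_with(alpha=0.5, mu1=0.5)

        def reduced(_t, y):
            I, S, R = y
            return [
                -p.k * p.alpha * I * S,
                -p.mu1 * p.k * S * (S + R) + p.alpha * p.k * I * S,
                p.mu1 * p.k * S * (S + R),
            ]

        init = [0.98, 0.02, 0, 0, 0]
        full = integrate(p, init, 30, n_out=31)
        ref = solve_ivp(reduced, (0, 30), [0.98, 0.02, 0.0], rtol=1e-8,
                        atol=1e-10, t_eval=full.times)
        assert np.all(full["V"] < 1e-10) and np.all(full["O"] < 1e-10)
        assert np.allclose(full["I"], ref.y[0], atol=1e-6)
        assert np.allclose(full["S"], ref.y[1], atol=1e-6)
        assert np.allclose(full["R"], ref.y[2], atol=1e-6)


class TestEquilibria:
    def test_only_rumor_free_family_is_feasible(self, defaults):
        eq = {e.label: e for e in equilibria(defaults)}
        assert eq["E1"].feasible
        assert not eq["E2"].feasible and not eq["E3"].feasible

    def test_rumor_free_members_are_stationary(self, defaults):
        for i1 in (0.0, 0.3, 1.0):
            r = isvor_rhs([i1, 0, 0, 0, 1 - i1], defaults, "as_printed")
            assert np.all(r == 0)

    def test_all_rates_zero_is_degenerate(self):
        eq = equilibria(params_with())
        assert all(e.degenerate for e in eq)


class TestStateVector:
    def test_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            StateVector(0.5, 0.5, 0.5, 0, 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            StateVector(1.2, -0.2, 0, 0, 0)

    def test_round_trips_through_array(self):
        s = StateVector(0.2, 0.3, 0.1, 0.15, 0.25)
        assert StateVector.from_array(s.as_array()) == s
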