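import numpy as np
import pytest
from scipy.optimize import brentq

from isvor import IsvorParams, ParameterError, jacobian_at_E1, stability_interval, stability_report
from isvor.meanfield import closed_form_bounds
from conftest import params_with


def random_params(rng: np.random.Generator, k: float = 10.0) -> IsvorParams:
    v = rng.random(11)
    return IsvorParams(alpha=v[0], epsilon=0.0, lam=v[1], mu1=v[2], mu2=v[3],
                       gamma=v[4], eta=v[5], xi1=v[6], xi2=v[7],
                       theta=v[8], beta1=v[9], beta2=v[10], k=k)


class TestJacobian:
    def test_entry_11_at_full_ignorance(self, defaults):
        # U1(I1=1) = alpha*k - xi1 - gamma = 5 - 0.8
        J = jacobian_at_E1(defaults, 1.0)
        assert J[0, 0] == pytest.approx(4.2)

    def test_zero_rates_give_zero_matrix(self):
        assert np.all(jacobian_at_E1(params_with(), 0.5) == 0)

    def test_entry_12_always_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            J = jacobian_at_E1(random_params(rng), rng.random())
            assert J[0, 1] == 0.0

    def test_I1_out_of_range_rejected(self, defaults):
        with pytest.raises(ParameterError):
            jacobian_at_E1(defaults, 1.5)


class TestStabilityReport:
    def test_u1_sign_change_at_default_threshold(self, defaults):
        # U1 = 0 at (mu1*k + xi1 + gamma) / (mu1*k + alpha*k) = 0.58
        assert stability_report(defaults, 0.58).U1 == pytest.approx(0.0, abs=1e-12)
        assert stability_report(defaults, 0.57).U1 < 0
        assert stability_report(defaults, 0.59).U1 > 0

    def test_b_sign_change_at_default_threshold(self, defaults):
        # B = 0 at (beta1 + beta2) / theta = 0.8
        assert stability_report(defaults, 0.8).B == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_are_marginal(self):
        rep = stability_report(params_with(), 0.4)
        assert np.all(rep.eigenvalues == 0)
        assert rep.verdict == "marginal"

    def test_verdict_tracks_spectral_abscissa(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = random_params(rng)
            rep = stability_report(p, rng.random())
            mx = rep.eigenvalues.real.max()
            if mx < -1e-9:
                assert rep.verdict == "stable"
            elif mx > 1e-9:
                assert rep.verdict == "unstable"

    def test_hurwitz_determinants_match_printed_formulas(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            p = random_params(rng)
            i1 = rng.random()
            rep = stability_report(p, i1)
            u1, u2, b = rep.U1, rep.U2, rep.B
            assert rep.delta1 == pytest.approx(-(u1 + u2 + b))
            assert rep.delta2 == pytest.approx(
                -(u1 + u2 + b) * ((u1 + u2) * b + u1 * u2) - u1 * u2 * b
            )
            assert rep.delta3 == pytest.approx(-u1 * u2 * b)

    def test_discordant_draws_are_reported_not_hidden(self):
        # the triangular-cubic Hurwitz conditions are not equivalent to
        # eigenvalue stability once the off-diagonal couplings act; the
        # report must flag that discordance rather than fail silently
        rng = np.random.default_rng(101)
        reports = [stability_report(random_params(rng), rng.random())
                   for _ in range(400)]
        discordant = [r for r in reports if not r.hurwitz_concordant]
        for r in discordant:
            assert r.hurwitz_positive and r.verdict != "stable"
        # every concordance flag is consistent with its own fields
        for r in reports:
            assert r.hurwitz_concordant == (
                (not r.hurwitz_positive) or r.verdict == "stable"
            )


class TestStabilityInterval:
    def test_default_candidate_bounds(self, defaults):
        b = closed_form_bounds(defaults)
        assert b["u1_crossing"] == pytest.approx(0.58)
        assert b["b_crossing"] == pytest.approx(0.8)
        assert b["u2_crossing"] == pytest.approx(5.5 / 7)

    def test_crossings_match_independent_root_finding(self, defaults):
        p, k = defaults, defaults.k
        u1 = brentq(lambda x: p.mu1 * k * x - p.mu1 * k - p.xi1 - p.gamma
                    + p.alpha * k * x, 0, 1, xtol=1e-14)
        u2 = brentq(lambda x: p.mu2 * k * x - p.mu2 * k - p.xi2
                    + p.lam * k * x, 0, 1, xtol=1e-14)
        b = brentq(lambda x: p.theta * x - (p.beta1 + p.beta2), 0, 1, xtol=1e-14)
        bounds = closed_form_bounds(p)
        assert bounds["u1_crossing"] == pytest.approx(u1, abs=1e-10)
        assert bounds["u2_crossing"] == pytest.approx(u2, abs=1e-10)
        assert bounds["b_crossing"] == pytest.approx(b, abs=1e-10)

    def test_symmetric_rates_collapse_the_two_u_bounds(self):
        p = IsvorParams(mu1=0.4, mu2=0.4, alpha=0.3, lam=0.3,
                        xi1=0.2, gamma=0.1, xi2=0.3)
        b = closed_form_bounds(p)
        assert b["u1_crossing"] == pytest.approx(b["u2_crossing"])

    def test_theta_zero_makes_B_constant_negative(self, defaults):
        p = defaults.replace(theta=0.0)
        rep = stability_interval(p, grid=201)
        assert "b_crossing" not in rep.candidate_bounds
        for i1 in (0.0, 0.5, 1.0):
            assert stability_report(p, i1).B == pytest.approx(-0.2)

    def test_scan_boundaries_agree_with_pointwise_verdicts(self, defaults):
        rep = stability_interval(defaults, grid=401)
        assert not rep.degenerate
        for lo, hi in rep.stable_intervals:
            mid = 0.5 * (lo + hi)
            assert stability_report(defaults, mid).verdict == "stable"
        # just outside a refined boundary the verdict flips
        if rep.stable_intervals:
            lo, hi = rep.stable_intervals[0]
            if hi < 1.0:
                assert stability_report(defaults, min(hi + 1e-4, 1.0)).verdict != "stable"

    def test_degenerate_params_flagged(self):
        rep = stability_interval(params_with(), grid=51)
        assert rep.degenerate and rep.stable_intervals == ()
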