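import dataclasses

import numpy as np
import pytest
from scipy.interpolate import interp1d

from isvor import AbmConfig, Graph, IsvorParams, ParameterError, ensemble, exact_one_step, initialize, run
from isvor.abm import ROLE_CODES, RoleAssignment, step
from isvor.meanfield import integrate
from isvor.networks import complete_graph, star_graph
from conftest import params_with

I, S, V, O, R = (ROLE_CODES[r] for r in "ISVOR")


def assignment(*codes: int) -> RoleAssignment:
    return RoleAssignment(np.array(codes, dtype=np.int8))


class TestInitialize:
    def test_single_spreader(self, path3):
        ra = initialize(path3, AbmConfig(init_spreaders=1, seed=7))
        assert (ra.roles == S).sum() == 1 and (ra.roles == I).sum() == 2

    def test_explicit_node_list(self):
        g = complete_graph(5)
        ra = initialize(g, AbmConfig(init_spreaders=(0, 3)))
        assert set(np.flatnonzero(ra.roles == S)) == {0, 3}

    def test_no_room_for_ignorants_rejected(self, path3):
        with pytest.raises(ParameterError):
            initialize(path3, AbmConfig(init_spreaders=3))


class TestStep:
    def test_certain_infection_on_edge(self, edge_graph):
        cfg = AbmConfig(params=params_with(alpha=1.0))
        rng = np.random.default_rng(0)
        new, log = step(edge_graph, assignment(I, S), cfg, rng)
        assert list(new.roles) == [S, S]
        assert log["I>S"] == 1 and sum(log.values()) == 1

    def test_all_recovered_is_fixed_point(self, path3):
        cfg = AbmConfig()
        rng = np.random.default_rng(0)
        new, log = step(path3, assignment(R, R, R), cfg, rng)
        assert list(new.roles) == [R, R, R]
        assert all(v == 0 for v in log.values())

    def test_transition_log_balances_role_deltas(self):
        g = complete_graph(30)
        cfg = AbmConfig(seed=2, init_spreaders=5, t_max=20)
        res = run(g, cfg)
        counts = (res.trajectory.data * g.n_nodes).round().astype(int)
        for t, log in enumerate(res.transitions):
            delta = counts[t + 1] - counts[t]
            flow = np.zeros(5, dtype=int)
            for key, c in log.items():
                flow[ROLE_CODES[key[0]]] -= c
                flow[ROLE_CODES[key[2]]] += c
            assert np.array_equal(flow, delta)

    @pytest.mark.parametrize("mode", ["aggregate", "per_contact"])
    def test_modes_agree_with_single_qualifying_neighbor(self, edge_graph, mode):
        # with at most one qualifying contact the two semantics coincide
        cfg = AbmConfig(params=params_with(alpha=0.37), contact_mode=mode)
        dist = exact_one_step(edge_graph, assignment(I, S), cfg)
        assert dist[(S, S)] == pytest.approx(0.37)
        assert dist[(I, S)] == pytest.approx(0.63)


class TestExactOneStep:
    def test_edge_half_infection(self, edge_graph):
        cfg = AbmConfig(params=params_with(alpha=0.5))
        dist = exact_one_step(edge_graph, assignment(I, S), cfg)
        assert dist == {(S, S): pytest.approx(0.5), (I, S): pytest.approx(0.5)}

    def test_all_recovered_point_mass(self, path3):
        dist = exact_one_step(path3, assignment(R, R, R), AbmConfig())
        assert dist == {(R, R, R): pytest.approx(1.0)}

    def test_isolated_oyster_sequential_trials(self, isolated):
        cfg = AbmConfig(params=params_with(theta=0.25, beta1=0.1, beta2=0.1))
        dist = exact_one_step(isolated, assignment(O), cfg)
        assert dist[(R,)] == pytest.approx(0.25)
        assert dist[(S,)] == pytest.approx(0.075)
        assert dist[(V,)] == pytest.approx(0.0675)
        assert dist[(O,)] == pytest.approx(0.6075)

    def test_isolated_spreader_sequential_trials(self, isolated):
        cfg = AbmConfig(params=params_with(gamma=0.3, xi1=0.5))
        dist = exact_one_step(isolated, assignment(S), cfg)
        assert dist[(V,)] == pytest.approx(0.3)
        assert dist[(O,)] == pytest.approx(0.35)
        assert dist[(S,)] == pytest.approx(0.35)

    @pytest.mark.parametrize("mode", ["aggregate", "per_contact"])
    @pytest.mark.parametrize("codes", [(I, S, V), (S, V, O), (I, I, S), (V, O, R)])
    def test_distribution_sums_to_one(self, path3, mode, codes):
        cfg = AbmConfig(contact_mode=mode)
        dist = exact_one_step(path3, assignment(*codes), cfg)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_too_large_graph_rejected(self):
        g = complete_graph(9)
        with pytest.raises(ParameterError):
            exact_one_step(g, RoleAssignment(np.zeros(9, dtype=np.int8)), AbmConfig())


class TestRunInvariants:
    @pytest.mark.parametrize("mode", ["aggregate", "per_contact"])
    def test_conservation_and_monotone_absorbing_roles(self, mode):
        g = complete_graph(40)
        cfg = AbmConfig(seed=9, init_spreaders=3, t_max=60, contact_mode=mode)
        res = run(g, cfg)
        counts = (res.trajectory.data * g.n_nodes).round(8)
        assert np.allclose(counts.sum(axis=1), g.n_nodes)
        r = res.trajectory["R"]
        i = res.trajectory["I"]
        assert np.all(np.diff(r) >= -1e-12)  # R has no outflow
        assert np.all(np.diff(i) <= 1e-12)   # I has no inflow

    def test_absorbing_state_stops_the_run(self):
        g = complete_graph(25)
        cfg = AbmConfig(seed=1, t_max=10_000)
        res = run(g, cfg)
        assert res.absorbed
        final = res.trajectory.final()
        assert final["S"] == final["V"] == final["O"] == 0.0
        assert final["I"] + final["R"] == pytest.approx(1.0, abs=1e-12)

    def test_no_infection_path_leaves_ignorants_untouched(self):
        # with alpha = lam = 0 the single spreader is the only active node
        g = complete_graph(20)
        p = params_with(gamma=0.3, xi1=0.5, mu1=0.5, theta=0.25,
                        beta1=0.1, beta2=0.1, mu2=0.5, xi2=0.5)
        cfg = AbmConfig(params=p, seed=4, t_max=500)
        res = run(g, cfg)
        assert res.trajectory["I"][-1] == pytest.approx(19 / 20)
        assert res.trajectory["R"][-1] == pytest.approx(1 / 20)

    def test_bit_identical_under_same_seed(self):
        g = complete_graph(50)
        cfg = AbmConfig(seed=123, init_spreaders=2, t_max=30)
        a, b = run(g, cfg), run(g, cfg)
        assert np.array_equal(a.trajectory.data, b.trajectory.data)
        assert a.transitions == b.transitions


class TestEnsemble:
    def test_single_rep_equals_single_run(self):
        g = complete_graph(30)
        cfg = AbmConfig(seed=5, t_max=20)
        ens = ensemble(g, cfg, reps=1)
        solo = run(g, cfg, np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0]))
        assert np.array_equal(ens.data, solo.trajectory.data)

    def test_mean_final_mass_exactly_conserved(self):
        g = complete_graph(60)
        cfg = AbmConfig(seed=8, t_max=200)
        ens = ensemble(g, cfg, reps=20)
        assert ens["I"][-1] + ens["R"][-1] == pytest.approx(1.0, abs=1e-12)

    def test_padding_repeats_absorbing_values(self):
        g = complete_graph(30)
        cfg = AbmConfig(seed=8, t_max=500)
        ens, runs = ensemble(g, cfg, reps=5, return_runs=True)
        assert len(ens) == max(len(r.trajectory) for r in runs)
        assert all(r.absorbed for r in runs)


class TestMeanFieldCorrespondence:
    def test_complete_graph_tracks_conserving_flow(self):
        """Well-mixed sanity link: per-contact dynamics with rates rescaled
        to match the degree-(n-1) mass action, run on a slowed time scale,
        stay within 0.05 sup-norm of the conserving mean-field solution."""
        n, c, frac = 500, 0.02, 0.05
        p = IsvorParams()
        scaled = {f: c * getattr(p, f) for f in p.probability_fields}
        for f in ("alpha", "lam", "mu1", "mu2", "eta"):
            scaled[f] = c * getattr(p, f) * p.k / (n - 1)
        cfg = AbmConfig(params=IsvorParams(**scaled, k=p.k),
                        init_spreaders=int(n * frac),
                        contact_mode="per_contact",
                        t_max=int(40 / c), seed=42)
        tr = ensemble(complete_graph(n), cfg, reps=10)
        ode = integrate(p, [1 - frac, frac, 0, 0, 0], t_max=40, n_out=801,
                        variant="conserving")
        sup = 0.0
        for col in tr.columns:
            f = interp1d(ode.times, ode[col], bounds_error=False,
                         fill_value=(ode[col][0], ode[col][-1]))
            sup = max(sup, float(np.abs(tr[col] - f(c * tr.times)).max()))
        assert sup < 0.05
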