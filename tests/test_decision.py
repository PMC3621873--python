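"""Decision model: cost minimization, social impact, and steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxgame as vg
from vaxgame.decision import ACCEPT, REJECT, DecisionState

from conftest import make_network, rng_for


class TestInitialization:
    @pytest.mark.parametrize("w0,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_willingness(self, star, w0, expected):
        state = vg.initialize_decisions(star, w0, rng_for(0))
        assert vg.coverage(state) == expected

    def test_half_willingness_within_binomial_interval(self, highschool):
        state = vg.initialize_decisions(highschool, 0.5, rng_for(1))
        # 99% binomial interval for n=800, p=0.5: 0.5 +- 2.58*sqrt(.25/800)
        half_width = 2.58 * math.sqrt(0.25 / 800)
        assert abs(vg.coverage(state) - 0.5) < half_width

    def test_reproducible_under_fixed_seed(self, highschool):
        a = vg.initialize_decisions(highschool, 0.3, rng_for(2))
        b = vg.initialize_decisions(highschool, 0.3, rng_for(2))
        assert np.array_equal(a.decisions, b.decisions)


class TestPerceivedRisk:
    def test_all_neighbors_vaccinated_zero_risk(self, star):
        state = DecisionState(np.array([-1, 1, 1, 1, 1]))
        assert vg.perceived_risk(0, state, star, 0.4368) == 0.0

    def test_no_neighbor_vaccinated_full_rate(self, star):
        state = DecisionState(np.array([1, -1, -1, -1, -1]))
        assert vg.perceived_risk(0, state, star, 0.4368) == 0.4368

    def test_one_of_four_unvaccinated(self, star):
        state = DecisionState(np.array([-1, -1, 1, 1, 1]))
        assert vg.perceived_risk(0, state, star, 0.4368) == pytest.approx(0.1092)


class TestCostMinimizedChoice:
    @pytest.mark.parametrize(
        "lam,r,previous,expected",
        [
            (0.2, 0.1, REJECT, ACCEPT),   # risk dominates cost
            (0.05, 0.1, ACCEPT, REJECT),  # cost dominates risk
            (0.0, 0.0, REJECT, REJECT),   # herd-immunity free-riding tie
            (0.3, 0.3, ACCEPT, ACCEPT),   # generic tie keeps previous
        ],
    )
    def test_threshold_rule(self, lam, r, previous, expected):
        assert vg.cost_minimized_choice(lam, r, previous) == expected


class TestInfluence:
    def test_single_source_identity(self):
        net = make_network([(0, 1, 10.0)])
        state = DecisionState(np.array([-1, 1]))
        assert vg.influence_strengths(0, state, net) == (10.0, 0.0)

    def test_two_sources_diminishing(self):
        net = make_network([(0, 1, 2.0), (0, 2, 8.0)])
        state = DecisionState(np.array([-1, 1, 1]))
        i_plus, i_minus = vg.influence_strengths(0, state, net)
        assert i_plus == pytest.approx(10 / math.sqrt(2))
        assert i_minus == 0.0

    def test_exponent_one_gives_plain_sum(self):
        net = make_network([(0, 1, 2.0), (0, 2, 8.0)])
        state = DecisionState(np.array([-1, 1, 1]))
        i_plus, _ = vg.influence_strengths(0, state, net, sit_exponent=1.0)
        assert i_plus == 10.0

    def test_discrepancy_examples(self):
        assert vg.normalized_discrepancy(3.0, 3.0) == 0.0
        assert vg.normalized_discrepancy(5.0, 0.0) == 1.0
        assert vg.normalized_discrepancy(0.0, 0.0) == 0.0
        assert vg.normalized_discrepancy(10 / math.sqrt(2), 3.0) == pytest.approx(
            0.4042, abs=1e-4
        )

    def test_label_swap_antisymmetry(self, triangle):
        """Swapping every decision negates the discrepancy at each node."""
        state = DecisionState(np.array([1, -1, 1]))
        flipped = DecisionState(-state.decisions)
        for node in range(3):
            ip, im = vg.influence_strengths(node, state, triangle)
            ip2, im2 = vg.influence_strengths(node, flipped, triangle)
            assert vg.normalized_discrepancy(ip, im) == pytest.approx(
                -vg.normalized_discrepancy(ip2, im2)
            )


class TestFermi:
    def test_midpoint(self):
        assert vg.opinion_probability(0.0, 0.1) == 0.5

    def test_closed_form_value(self):
        assert vg.opinion_probability(0.5, 0.5) == pytest.approx(
            1 / (1 + math.exp(-1))
        )

    def test_sharp_responsiveness_dominance(self):
        assert vg.opinion_probability(0.5, 1e-3) > 1 - 1e-12

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            vg.opinion_probability(0.1, 0.0)

    @given(
        delta=st.floats(-1, 1),
        kappa=st.floats(1e-3, 10.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetry(self, delta, kappa):
        q = vg.opinion_probability(delta, kappa)
        assert q + vg.opinion_probability(-delta, kappa) == pytest.approx(1.0)


class TestFinalDecision:
    def test_pure_cost_decider(self):
        rng = rng_for(3)
        assert all(
            vg.final_decision(ACCEPT, REJECT, 0.0, rng) == ACCEPT
            for _ in range(100)
        )

    def test_absolute_social_follower(self):
        rng = rng_for(4)
        assert all(
            vg.final_decision(ACCEPT, REJECT, 1.0, rng) == REJECT
            for _ in range(100)
        )

    def test_half_conformity_monte_carlo(self):
        rng = rng_for(5)
        n = 10_000
        social = sum(
            vg.final_decision(ACCEPT, REJECT, 0.5, rng) == REJECT
            for _ in range(n)
        )
        assert abs(social / n - 0.5) < 3 * math.sqrt(0.25 / n)


class TestStep:
    def test_cost_exceeded_everywhere_gives_rejection(self, highschool):
        """When r > beta_perc no perceived risk can justify the vaccine."""
        params = vg.DecisionParams(r=0.9, p=0.0, beta_perc=0.4368)
        state = vg.initialize_decisions(highschool, 0.5, rng_for(6))
        nxt = vg.step(state, highschool, params, rng_for(7))
        assert vg.coverage(nxt) == 0.0

    def test_deterministic_at_p_zero(self, highschool):
        """The synchronous pure-cost map consumes no randomness at all."""
        params = vg.DecisionParams(r=0.2, p=0.0, update_scheme="synchronous")
        state = vg.initialize_decisions(highschool, 0.5, rng_for(8))
        a = vg.step(state, highschool, params, rng_for(9))
        b = vg.step(state, highschool, params, rng_for(10))
        assert np.array_equal(a.decisions, b.decisions)

    def test_star_hub_converts_to_leaf_consensus(self, star):
        params = vg.DecisionParams(
            r=0.5, p=1.0, kappa=1e-3, update_scheme="synchronous"
        )
        state = DecisionState(np.array([-1, 1, 1, 1, 1]))
        nxt = vg.step(state, star, params, rng_for(11))
        assert nxt.decisions[0] == ACCEPT

    def test_tie_rule_free_riding_fixed_point(self, star):
        """An unvaccinated hub with fully vaccinated neighbors stays
        unvaccinated even at zero vaccine cost."""
        params = vg.DecisionParams(r=0.0, p=0.0)
        state = DecisionState(np.array([-1, 1, 1, 1, 1]))
        nxt = vg.step(state, star, params, rng_for(12))
        assert nxt.decisions[0] == REJECT
        assert np.all(nxt.decisions[1:] == ACCEPT)

    def test_isolated_node_keeps_cost_choice(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        net = vg.ContactNetwork(g)
        params = vg.DecisionParams(r=0.3, p=1.0)
        state = DecisionState(np.array([1, 1, 1]))
        nxt = vg.step(state, net, params, rng_for(13))
        # isolated node 2: lambda=0 < r, no social sources -> cost rejection
        assert nxt.decisions[2] == REJECT


class TestRun:
    def test_unanimous_acceptance_is_fixed_point_at_zero_cost(self, small_net):
        params = vg.DecisionParams(r=0.0, p=0.0, w0=1.0)
        res = vg.run(small_net, params, rng_for(14))
        assert res.coverage == 1.0
        assert res.termination_reason == "fixed_point"

    def test_prohibitive_cost_empties_coverage(self, small_net):
        params = vg.DecisionParams(r=0.9, p=0.0, w0=0.5)
        res = vg.run(small_net, params, rng_for(15))
        assert res.coverage == 0.0
        assert res.termination_reason == "fixed_point"

    def test_p_zero_bit_reproducible(self, highschool, highschool_ws):
        params = vg.DecisionParams(r=0.2, p=0.0, w0=0.5)
        runs = [
            vg.run(highschool, params, rng_for(16), workspace=highschool_ws)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].trajectory, runs[1].trajectory)
        assert np.array_equal(
            runs[0].final_state.decisions, runs[1].final_state.decisions
        )

    def test_p_zero_coverage_non_increasing_in_r(self, highschool, highschool_ws):
        init = vg.initialize_decisions(highschool, 0.5, rng_for(17))
        covs = []
        for r in np.linspace(0.0, 1.0, 11):
            params = vg.DecisionParams(r=float(r), p=0.0)
            res = vg.run(
                highschool, params, rng_for(18), initial=init,
                workspace=highschool_ws,
            )
            covs.append(res.coverage)
        assert all(a >= b - 1e-12 for a, b in zip(covs, covs[1:]))

    def test_p_one_trajectory_independent_of_r(self, small_net):
        """Absolute social followers never consult the cost rule: identical
        seeds give identical trajectories whatever the cost ratio."""
        trajs = []
        for r in (0.1, 0.5, 0.9):
            params = vg.DecisionParams(r=r, p=1.0, w0=0.5, max_iters=50, window=10)
            trajs.append(vg.run(small_net, params, rng_for(19)).trajectory)
        assert np.array_equal(trajs[0], trajs[1])
        assert np.array_equal(trajs[1], trajs[2])

    def test_permutation_invariance(self):
        """Relabeling nodes and the initial state identically leaves the
        deterministic coverage trajectory unchanged."""
        edges = [(0, 1, 4.0), (1, 2, 1.0), (2, 3, 7.0), (3, 0, 2.0), (0, 2, 5.0)]
        net = make_network(edges)
        perm = [2, 0, 3, 1]
        net2 = make_network([(perm[u], perm[v], w) for u, v, w in edges])
        init = np.array([1, -1, -1, 1])
        init2 = np.empty(4, dtype=int)
        for i, d in enumerate(init):
            init2[perm[i]] = d
        params = vg.DecisionParams(r=0.25, p=0.0, update_scheme="synchronous")
        res = vg.run(net, params, rng_for(20), initial=DecisionState(init))
        res2 = vg.run(net2, params, rng_for(21), initial=DecisionState(init2))
        assert np.array_equal(res.trajectory, res2.trajectory)

    def test_synchronous_scheme_runs(self, small_net):
        params = vg.DecisionParams(
            r=0.2, p=0.3, w0=0.5, max_iters=20, window=5,
            update_scheme="synchronous",
        )
        res = vg.run(small_net, params, rng_for(22))
        assert 0.0 <= res.coverage <= 1.0
        assert len(res.trajectory) == 21

    def test_synchronous_parity_cycle_detected(self, highschool, highschool_ws):
        """The synchronous pure-cost map overshoots into the global
        vaccinate/abstain alternation; it is reported as a 2-cycle with
        cycle-averaged coverage."""
        params = vg.DecisionParams(r=0.1, p=0.0, update_scheme="synchronous")
        res = vg.run(highschool, params, rng_for(24), workspace=highschool_ws)
        assert res.termination_reason == "two_cycle"
        assert res.coverage == pytest.approx(res.trajectory[-2:].mean())

    def test_window_mean_reported_for_stochastic_runs(self, small_net):
        params = vg.DecisionParams(r=0.2, p=0.5, w0=0.5, max_iters=60, window=20)
        res = vg.run(small_net, params, rng_for(23))
        assert res.coverage == pytest.approx(res.trajectory[-20:].mean())


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": -0.1},
            {"p": 1.5},
            {"kappa": 0.0},
            {"w0": -0.2},
            {"beta_perc": 1.2},
            {"max_iters": 10, "window": 20},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            vg.DecisionParams(**kwargs)
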