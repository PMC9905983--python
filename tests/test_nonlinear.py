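"""Curved-cost equilibria: stationary roots, bifurcations, flows, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tocsim import (
    AgentSpec,
    CostModel,
    Population,
    ProductivityModel,
    allocate_investments,
    best_response_oracle,
    cooperative_state,
    decimate,
    frozen_bifurcation_diagram,
    gradient_flow,
    grid_population,
    random_population,
    saddle_node_threshold,
    self_consistent_state,
    solve_total_investment,
    stationary_roots,
)

EXP = ProductivityModel.exponential()


def quadratic_residual(x, c, gamma, c_max):
    """Stationarity in polynomial form: 1 + x(gamma-1) - gamma x^2 = c/c_max."""
    return 1 + x * (gamma - 1) - gamma * x * x - c / c_max


class TestStationaryRoots:
    @given(
        gamma=st.floats(-0.9, 3.0).filter(lambda g: abs(g) > 1e-3),
        c=st.floats(0.02, 0.5),
        x_tot=st.floats(0.2, 2.5),
    )
    def test_roots_satisfy_the_quadratic(self, gamma, c, x_tot):
        c_max = math.exp(-x_tot)
        roots = stationary_roots(c, gamma, c_max)
        if roots.discriminant < 0:
            return
        assert roots.root_minus <= roots.root_plus
        for r in (roots.root_minus, roots.root_plus):
            assert quadratic_residual(r, c, gamma, c_max) == pytest.approx(0.0, abs=1e-10)

    def test_stable_branch_labels(self):
        assert stationary_roots(0.1, 0.5, 0.2).stable == "plus"
        assert stationary_roots(0.1, -0.5, 0.2).stable == "minus"

    def test_linear_limit_recovered(self):
        roots = stationary_roots(0.1, 1e-9, 0.2)
        assert roots.stable_root == pytest.approx(0.5, abs=1e-6)

    def test_threshold_structure_at_gamma_one(self):
        # gamma = 1 kills the linear term: roots are +-sqrt((c_max-c)/c_max)
        c_max = 0.2
        roots = stationary_roots(c_max, 1.0, c_max)
        assert roots.stable_root == pytest.approx(0.0, abs=1e-12)
        assert roots.root_minus == pytest.approx(-roots.root_plus, abs=1e-12)

    def test_protected_region_has_real_roots(self):
        # gamma=1.5: c_node/c_max = 25/24, so c = 1.03 c_max still has both roots
        c_max = 0.15
        roots = stationary_roots(1.03 * c_max, 1.5, c_max)
        assert roots.discriminant > 0
        assert roots.root_minus > 0 and roots.root_plus > 0
        beyond = stationary_roots(1.05 * c_max, 1.5, c_max)
        assert beyond.discriminant < 0 and beyond.stable_root is None

    @given(
        gamma=st.floats(0.1, 3.0),
        c_max=st.floats(0.05, 0.6),
        frac=st.floats(0.1, 0.999),
    )
    def test_branch_stability_against_second_derivative(self, gamma, c_max, frac):
        # flow stability at frozen total investment: d(grad)/dx < 0 on the
        # stable root, > 0 on the unstable one
        c = frac * saddle_node_threshold(c_max, gamma).c_node
        roots = stationary_roots(c, gamma, c_max)
        if roots.discriminant <= 1e-8:
            return

        def dgrad_dx(x):
            return -c_max + c * gamma / (1 + gamma * x) ** 2

        assert dgrad_dx(roots.stable_root) < 0
        if roots.unstable_root > -1 / gamma:  # inside the cost domain
            assert dgrad_dx(roots.unstable_root) > 0


class TestSaddleNode:
    def test_threshold_values(self):
        assert saddle_node_threshold(0.2, 1.0).c_node == pytest.approx(0.2)
        assert saddle_node_threshold(0.12, 1.5).c_node == pytest.approx(0.125)
        assert saddle_node_threshold(0.12, 1.5).x_node == pytest.approx(1.0 / 6.0)

    def test_node_dominates_threshold_and_diverges_for_small_gamma(self):
        c_max = 0.3
        nodes = [saddle_node_threshold(c_max, g).c_node for g in (2.0, 1.5, 1.0, 0.5, 0.1, 0.01)]
        assert all(n >= c_max - 1e-15 for n in nodes)
        assert nodes[2] == pytest.approx(c_max)
        assert nodes[-1] > nodes[-2] > nodes[-3]  # grows without bound as gamma -> 0

    def test_discriminant_vanishes_at_the_node(self):
        for gamma, c_max in [(1.5, 0.12), (0.7, 0.3), (2.5, 0.05)]:
            c_node = saddle_node_threshold(c_max, gamma).c_node
            roots = stationary_roots(c_node, gamma, c_max)
            assert roots.discriminant == pytest.approx(0.0, abs=1e-12)

    def test_square_root_approach_to_the_node(self):
        # x(c) - x_node ~ sqrt(c_node - c) over two decades near the bifurcation
        gamma, c_max = 1.5, 0.15
        bp = saddle_node_threshold(c_max, gamma)
        eps = np.geomspace(1e-6, 1e-4, 12) * bp.c_node
        dx = np.array(
            [stationary_roots(bp.c_node - e, gamma, c_max).stable_root - bp.x_node for e in eps]
        )
        slope = np.polyfit(np.log(eps), np.log(dx), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)


class TestSelfConsistentState:
    def test_tiny_gamma_matches_linear_equilibrium(self):
        pop_lin = grid_population(0.15, 0.01, 8)
        x_lin = solve_total_investment(8, pop_lin.c_mean)
        lin_state = allocate_investments(pop_lin, x_lin)
        pop = grid_population(0.15, 0.01, 8, cost=CostModel.logarithmic(1e-9))
        state = self_consistent_state(pop)
        assert state.x_tot == pytest.approx(x_lin, abs=1e-6)
        assert np.allclose(state.x, lin_state.x, atol=1e-6)

    def test_single_agent_fixed_point_oracle(self):
        # gamma=1: the stationarity reduces to x = sqrt((c_max - c)/c_max)
        # with c_max = e^{-x}; solve that scalar fixed point by bisection
        c = 0.15
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            c_max = math.exp(-mid)
            if math.sqrt(max(c_max - c, 0.0) / c_max) > mid:
                lo = mid
            else:
                hi = mid
        expected = 0.5 * (lo + hi)
        pop = Population((AgentSpec(0, c),), EXP, CostModel.logarithmic(1.0))
        state = self_consistent_state(pop)
        assert state.x_tot == pytest.approx(expected, abs=1e-10)

    def test_self_consistency_closes(self):
        pop = grid_population(0.1, 0.02, 6, cost=CostModel.logarithmic(0.8))
        state = self_consistent_state(pop)
        assert state.c_max == pytest.approx(math.exp(-state.x_tot), abs=1e-14)
        assert state.x.sum() == pytest.approx(state.x_tot, abs=1e-9)

    def test_gamma_continuity_brackets_linear(self):
        pop_lin = grid_population(0.15, 0.01, 5)
        x_lin = solve_total_investment(5, pop_lin.c_mean)
        x_minus = self_consistent_state(
            grid_population(0.15, 0.01, 5, cost=CostModel.logarithmic(-1e-6))
        ).x_tot
        x_plus = self_consistent_state(
            grid_population(0.15, 0.01, 5, cost=CostModel.logarithmic(1e-6))
        ).x_tot
        assert min(x_minus, x_plus) - 1e-4 < x_lin < max(x_minus, x_plus) + 1e-4
        assert abs(x_plus - x_lin) < 1e-4 and abs(x_minus - x_lin) < 1e-4


class TestGradientFlow:
    def test_fixed_point_is_stationary(self):
        pop = grid_population(0.15, 0.01, 5, cost=CostModel.logarithmic(0.5))
        state = self_consistent_state(pop)
        flow_state, summary = gradient_flow(pop, state.x)
        assert np.allclose(flow_state.x, state.x, atol=1e-7)

    @given(seed=st.integers(0, 500))
    def test_converges_to_closed_form_linear_state(self, seed):
        rng = np.random.default_rng(seed)
        pop = random_population(6, rng, low=0.1, high=0.35)
        res = decimate(pop)
        x0 = rng.uniform(0.01, 0.5, size=res.population.n)
        flow_state, _ = gradient_flow(res.population, x0)
        assert flow_state.x_tot == pytest.approx(res.state.x_tot, abs=1e-6)
        assert np.allclose(flow_state.x, res.state.x, atol=1e-6)

    def test_complementarity_at_convergence(self):
        pop = grid_population(0.15, 0.02, 10, oligarch_c=0.1,
                              cost=CostModel.logarithmic(0.5))
        x0 = np.full(pop.n, 0.1)
        state, summary = gradient_flow(pop, x0)
        grads = pop.rs * (1 - state.x) * math.exp(-state.x_tot) - pop.costs / (
            1 + pop.gammas * state.x
        )
        active = state.x > 0
        assert np.all(np.abs(grads[active]) < 1e-8)
        assert np.all(grads[~active] <= 1e-10)

    def test_sudden_death_exit_beyond_the_node(self):
        # push the costliest survivor just past c_node: its investment
        # collapses to zero instead of fading linearly
        gamma = 1.5
        pop = grid_population(0.15, 0.002, 50, oligarch_c=0.1,
                              cost=CostModel.logarithmic(gamma))
        res = decimate(pop, solver="nonlinear")
        state = res.state
        costs = res.population.costs.copy()
        worst = int(np.argmax(costs))
        assert costs[worst] > state.c_max  # it sat in the protected region
        costs[worst] = state.c_node * 1.02
        bumped = Population.from_costs(costs, cost=CostModel.logarithmic(gamma))
        new_state, _ = gradient_flow(bumped, state.x)
        assert new_state.x[worst] == 0.0
        assert not new_state.survivors[worst]

    def test_negative_start_rejected(self):
        pop = grid_population(0.15, 0.01, 3)
        with pytest.raises(ValueError):
            gradient_flow(pop, np.array([-0.1, 0.2, 0.2]))


class TestFrozenDiagram:
    def test_flow_structure_across_the_thresholds(self):
        gamma, c_max = 1.5, 0.15
        c_node = saddle_node_threshold(c_max, gamma).c_node
        grid = np.array([0.8 * c_max, 0.5 * (c_max + c_node), 1.05 * c_node])
        d = frozen_bifurcation_diagram(gamma, c_max, grid)
        # below c_max: entry possible, flow positive at x = 0+
        assert d.flow_sign(grid[0], 1e-9) > 0
        # protected window (c_max, c_node): origin stable AND a stable branch
        assert d.flow_sign(grid[1], 1e-9) < 0
        assert np.isfinite(d.stable_branch[1]) and d.stable_branch[1] > 0
        # beyond c_node: no stationary point, all flow towards zero
        assert np.isnan(d.stable_branch[2])
        for x in (0.05, 0.2, 0.5):
            assert d.flow_sign(grid[2], x) < 0

    def test_flow_signs_match_gradient_flow_direction(self):
        gamma, c_max = 1.5, 0.15
        x_tot = -math.log(c_max)
        c_probe, x_probe = 0.9 * c_max, 0.05
        d = frozen_bifurcation_diagram(gamma, c_max, np.array([c_probe]))
        # a lone perturbed agent in a frozen background moves the same way
        pop = Population.from_costs([c_probe], cost=CostModel.logarithmic(gamma))
        grad = pop.rs[0] * (1 - x_probe) * c_max - c_probe / (1 + gamma * x_probe)
        assert np.sign(grad) == d.flow_sign(c_probe, x_probe)

    def test_transcritical_point_at_c_max(self):
        gamma, c_max = 1.5, 0.2
        d = frozen_bifurcation_diagram(gamma, c_max, np.array([c_max]))
        # the unstable branch crosses x = 0 exactly at c = c_max
        assert min(abs(d.stable_branch[0]), abs(d.unstable_branch[0])) == pytest.approx(
            0.0, abs=1e-12
        )


class TestBestResponseOracle:
    def test_no_improvement_at_nash_states(self, grid50):
        res = decimate(grid50)
        for i in range(res.population.n):
            assert best_response_oracle(res.population, res.state, i) < 1e-8

    def test_perturbed_state_is_improvable(self, grid50):
        res = decimate(grid50)
        state = res.state
        state.x[0] *= 0.5
        state.x_tot = float(state.x.sum())
        assert best_response_oracle(res.population, state, 0) > 1e-6

    def test_cooperation_is_not_nash_for_heterogeneous_costs(self):
        pop = Population.from_costs([0.1, 0.3])
        state = cooperative_state(pop)
        assert best_response_oracle(pop, state, 0) > 1e-6
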