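"""Generations, chains, learning-curve estimation and the discrete optimum."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from intergen.agent import AllocationSchedule
from intergen.landscape import ArrowheadDesign, FitnessLandscape, expected_score
from intergen.simulate import (
    LearningCurve,
    estimate_learning_curve,
    optimal_tau,
    payoff_from_curve,
    run_actions,
    run_chain,
    run_generation,
    strategy_count,
)

QUIET = FitnessLandscape(optimum=(60.0, 50.0, 50.0), weights=(1.0, 1e-9, 1e-9), peak=1000.0, noise_sd=0.0)


class TestRunGeneration:
    def test_tau_zero_keeps_design_constant(self, default_land):
        land, init = default_land
        traj = run_generation(AllocationSchedule(0, 50), land, init, np.random.default_rng(0))
        assert all(r.design == init for r in traj.records)
        assert traj.n_explorations == 0

    def test_exploration_count_matches_schedule(self, default_land):
        land, init = default_land
        traj = run_generation(AllocationSchedule(7, 50), land, init, np.random.default_rng(1))
        assert traj.n_explorations == 7
        assert traj.T == 50 and traj.records[0].action == "exploit"

    def test_cumulative_score_sums_exploitation_trials(self, default_land):
        land, init = default_land
        traj = run_generation(AllocationSchedule(5, 50), land, init, np.random.default_rng(2))
        assert traj.W == sum(r.observed_score for r in traj.records if r.action == "exploit")
        assert all(r.observed_score is None for r in traj.records if r.action == "explore")

    def test_rejects_unknown_action(self, default_land):
        land, init = default_land
        with pytest.raises(ValueError, match="unknown action"):
            run_actions(["exploit", "rest"], land, init, np.random.default_rng(0))


class TestRunChain:
    def test_transmission_is_bit_exact(self, default_land):
        land, init = default_land
        first, second = run_chain(12, 12, land, init, np.random.default_rng(3))
        assert second.records[0].design == first.final_design

    def test_tau_zero_first_generation_transmits_initial_design(self, default_land):
        land, init = default_land
        first, second = run_chain(0, 5, land, init, np.random.default_rng(4))
        assert first.final_design == init
        assert second.records[0].design == init

    def test_asocial_baseline_restarts_from_common_design(self, default_land):
        # no transmission: two independent generations both begin at the fixed start
        land, init = default_land
        rng = np.random.default_rng(5)
        g1 = run_generation(AllocationSchedule(12, 50), land, init, rng)
        g2 = run_generation(AllocationSchedule(12, 50), land, init, rng)
        assert g1.records[0].design == init and g2.records[0].design == init


class TestLearningCurve:
    def test_g0_is_exactly_initial_efficiency(self, default_land):
        land, init = default_land
        curve = estimate_learning_curve(50, land, init, 0)
        assert curve.g[0] == expected_score(land, init)
        assert curve.se[0] == 0.0
        assert curve.tau_max == 24

    def test_same_seed_same_curve(self, default_land):
        land, init = default_land
        a = estimate_learning_curve(30, land, init, 9)
        b = estimate_learning_curve(30, land, init, 9)
        np.testing.assert_array_equal(a.g, b.g)

    def test_toy_zero_noise_curve_matches_independent_recursion(self):
        """Replay the agent rule in a tiny hand-coded simulator consuming the
        same random streams and compare g(tau) exactly."""
        n, T, L = 6, 11, 5
        init = (40, 50, 50)
        curve = estimate_learning_curve(n, QUIET, ArrowheadDesign(*init), 123, T=T, L=L)

        def efficiency(length):
            return 1000.0 - (length - 60.0) ** 2 - 1e-9 * (0.0)  # other attrs at optimum

        eff = np.empty((n, (T - 1) // 2 + 1))
        eff[:, 0] = efficiency(init[0])
        for i, child in enumerate(np.random.default_rng(123).spawn(n)):
            dirs = [1 - 2 * int(child.integers(0, 2)) for _ in range(3)]
            values = list(init)
            last_score, last_mod = None, None

            def hunt_round(vals, rng):
                exact = 1000.0 - (vals[0] - 60.0) ** 2 - 1e-9 * ((vals[1] - 50.0) ** 2 + (vals[2] - 50.0) ** 2)
                rng.normal(0.0, 0.0)  # stream-compatible no-op draw
                return int(round(max(0.0, exact)))

            last_score = hunt_round(values, child)
            for tau in range(1, (T - 1) // 2 + 1):
                k = int(child.integers(0, 3))
                values[k] = min(100, max(1, values[k] + dirs[k] * L))
                last_mod = k
                eff[i, tau] = 1000.0 - (values[0] - 60.0) ** 2 - 1e-9 * (
                    (values[1] - 50.0) ** 2 + (values[2] - 50.0) ** 2
                )
                score = hunt_round(values, child)
                if last_score is not None and score < last_score and last_mod is not None:
                    dirs[last_mod] *= -1
                last_score = score
        np.testing.assert_allclose(curve.g, eff.mean(axis=0), rtol=0, atol=1e-9)

    def test_rejects_empty_ensemble(self, default_land):
        land, init = default_land
        with pytest.raises(ValueError):
            estimate_learning_curve(0, land, init, 0)


class TestPayoffFromCurve:
    def test_no_exploration_payoff(self):
        g = np.array([10.0, 20.0, 30.0])
        assert payoff_from_curve(g, 0, 50, "unrepaid") == pytest.approx(50 * 10.0)
        assert payoff_from_curve(g, 0, 50, "repaid") == pytest.approx(100 * 10.0)

    @given(tau=st.integers(0, 24))
    def test_constant_curve_reduces_to_linear_decay(self, tau):
        g = np.full(25, 7.0)
        assert payoff_from_curve(g, tau, 50, "unrepaid") == pytest.approx((50 - tau) * 7.0)

    @given(tau=st.integers(0, 24))
    def test_repaid_exceeds_unrepaid_by_T_times_g(self, tau):
        rng = np.random.default_rng(0)
        g = np.cumsum(rng.uniform(0, 20, size=25)) + 100.0
        diff = payoff_from_curve(g, tau, 50, "repaid") - payoff_from_curve(g, tau, 50, "unrepaid")
        assert diff == pytest.approx(50 * g[tau])

    def test_out_of_range_tau_rejected(self):
        g = np.full(25, 1.0)
        with pytest.raises(ValueError):
            payoff_from_curve(g, 25, 50, "unrepaid")
        with pytest.raises(ValueError):
            payoff_from_curve(g, -1, 50, "unrepaid")


class TestOptimalTau:
    def test_constant_curve_prefers_no_exploration(self):
        sol = optimal_tau(np.full(25, 5.0), 50, "unrepaid")
        assert sol.tau_star == 0
        assert len(sol.per_trial_payoff) == 25

    def test_tie_breaks_toward_smaller_tau(self):
        # g rising then flat: repaid pay-off plateaus; first maximum wins
        g = np.array([1.0, 1.0, 1.0])
        sol = optimal_tau(g, 7, "unrepaid")
        assert sol.tau_star == 0

    def test_repaid_explores_at_least_as_much_on_random_landscapes(self):
        """Discrete analogue of the continuous theorem, on a randomized battery."""
        rng = np.random.default_rng(2024)
        for _ in range(5):
            w = rng.uniform(0.05, 0.4, size=3)
            init = ArrowheadDesign(*(int(v) for v in rng.integers(20, 45, size=3)))
            opt = tuple(float(v) for v in rng.integers(55, 85, size=3))
            land = FitnessLandscape(optimum=opt, weights=tuple(w), peak=1000.0, noise_sd=5.0)
            curve = estimate_learning_curve(400, land, init, rng)
            assert not np.allclose(curve.g, curve.g[0])
            u = optimal_tau(curve, 50, "unrepaid").tau_star
            r = optimal_tau(curve, 50, "repaid").tau_star
            assert r >= u

    def test_monte_carlo_payoff_matches_curve_expectation(self, default_land):
        """Simulating full trajectories at fixed tau agrees with the curve-based
        expected pay-off within Monte-Carlo error."""
        land, init = default_land
        tau = 12
        curve = estimate_learning_curve(4000, land, init, 31)
        expected = payoff_from_curve(curve, tau, 50, "unrepaid")
        rng = np.random.default_rng(32)
        sims = [
            run_generation(AllocationSchedule(tau, 50), land, init, rng).W for _ in range(800)
        ]
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - expected) < 3 * se + 50.0


def test_strategy_count_is_exact_power_of_two():
    assert strategy_count(50) == 2**49 == 562_949_953_421_312
    assert strategy_count(1) == 1
    with pytest.raises(ValueError):
        strategy_count(0)
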