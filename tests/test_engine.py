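"""Stochastic engine: transition sets, Gillespie steps, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from bkmc import (
    gillespie_step,
    make_fixture,
    parse_config,
    parse_model,
    run_ensemble,
    sample_initial_state,
    simulate_trajectory,
    transitions,
)
from bkmc.dsl import SimulationConfig
from bkmc.engine import RateCache

from conftest import load_fixture


def rng(seed=0):
    return np.random.default_rng(seed)


class TestTransitions:
    def test_toy_cycle_state_has_two_exits(self, toy_fast):
        model, _ = toy_fast
        # [ABC]=[001]: A can switch on (rate 1), C can escape down (rate 10)
        state = 1 << model.index["C"]
        ts = transitions(model, state)
        assert ts.nodes == (model.index["A"], model.index["C"])
        assert list(ts.rates) == [1.0, 10.0]
        assert ts.total_rate == 11.0
        assert all(bin(t ^ state).count("1") == 1 for t in ts.targets)

    def test_fixed_point_has_no_exits(self, toy_fast):
        model, _ = toy_fast
        ts = transitions(model, 0)
        assert len(ts) == 0 and ts.total_rate == 0.0

    def test_single_node_constant_rate(self):
        model = parse_model("node A { rate_up = 2.0; rate_down = 0.5; }")
        ts = transitions(model, 0)
        assert list(ts.rates) == [2.0] and ts.targets == (1,)
        ts = transitions(model, 1)
        assert list(ts.rates) == [0.5] and ts.targets == (0,)

    def test_cache_is_bit_identical_to_direct_evaluation(self, toy_slow):
        model, _ = toy_slow
        cache = RateCache(model)
        for s in range(8):
            direct = transitions(model, s)
            cached = cache.transition_set(s)
            again = cache.transition_set(s)
            assert cached is again
            assert np.array_equal(direct.rates, cached.rates)
            assert direct.targets == cached.targets


class TestGillespieStep:
    def test_holding_time_closed_form(self, toy_fast):
        model, _ = toy_fast
        ts = transitions(model, 1 << model.index["C"])  # total rate 11
        dt, _ = gillespie_step(ts, u=math.exp(-11.0), u2=0.5)
        assert dt == pytest.approx(1.0, rel=1e-12)

    def test_cumulative_selection_rule(self, toy_fast):
        model, _ = toy_fast
        ts = transitions(model, 1 << model.index["C"])  # rates (1, 10)
        _, nxt = gillespie_step(ts, u=0.5, u2=0.5)  # 0.5*11 = 5.5 in (1, 11]
        assert nxt == ts.targets[1]
        _, nxt = gillespie_step(ts, u=0.5, u2=1.0 / 11.0)  # boundary <= picks first
        assert nxt == ts.targets[0]
        _, nxt = gillespie_step(ts, u=0.5, u2=1.0)
        assert nxt == ts.targets[1]

    def test_empty_transition_set_rejected(self, toy_fast):
        model, _ = toy_fast
        with pytest.raises(ValueError, match="absorbing"):
            gillespie_step(transitions(model, 0), 0.5, 0.5)

    def test_selection_frequencies_match_jump_chain(self, toy_fast):
        model, _ = toy_fast
        ts = transitions(model, 1 << model.index["C"])
        r = rng(42)
        draws = r.random(20000)
        hits = sum(gillespie_step(ts, 0.5, 1 - u)[1] == ts.targets[0] for u in draws)
        # target 0 carries rate 1 of 11
        assert hits / 20000 == pytest.approx(1 / 11, abs=4 * math.sqrt(0.09 / 20000))


class TestInitialState:
    def test_all_inputs_fixed_is_deterministic(self):
        model = parse_model(
            "node A { rate_up = 0; rate_down = 0; }\nnode B { rate_up = 0; rate_down = 0; }"
        )
        model.node("A").initial = "fixed-1"
        model.node("B").initial = "fixed-0"
        states = {sample_initial_state(model, rng(i)) for i in range(20)}
        assert states == {0b01}

    def test_free_nodes_uniform(self):
        model = parse_model(
            "\n".join(f"node N{i} {{ rate_up = 0; rate_down = 0; }}" for i in range(3))
        )
        r = rng(7)
        counts = np.zeros(8)
        for _ in range(100_000):
            counts[sample_initial_state(model, r)] += 1
        assert sps.chisquare(counts).pvalue > 1e-3

    def test_mixed_fixed_and_free(self):
        model = parse_model(
            "\n".join(f"node N{i} {{ rate_up = 0; rate_down = 0; }}" for i in range(3))
        )
        model.node("N0").initial = "fixed-1"
        r = rng(11)
        counts = {}
        for _ in range(40_000):
            s = sample_initial_state(model, r)
            counts[s] = counts.get(s, 0) + 1
        assert set(counts) == {0b001, 0b011, 0b101, 0b111}
        assert sps.chisquare(list(counts.values())).pvalue > 1e-3


class TestTrajectories:
    def test_absorbing_model_holds_initial_state(self):
        model = parse_model("node A { rate_up = 0.0; rate_down = 0.0; }")
        config = SimulationConfig(timetick=1.0, max_time=5.0, sample_count=1)
        traj = simulate_trajectory(model, config, rng(1))
        assert len(traj.times) == 1 and traj.horizon == 5.0

    def test_first_jump_time_is_exponential(self):
        # off -> on at rate 3, then absorbing
        model = parse_model("node A { rate_up = 3.0; rate_down = 0.0; }")
        model.node("A").initial = "fixed-0"
        config = SimulationConfig(timetick=1.0, max_time=50.0, sample_count=1)
        r = rng(5)
        times = []
        for _ in range(10_000):
            traj = simulate_trajectory(model, config, r)
            assert len(traj.times) == 2
            times.append(traj.times[1])
        assert sps.kstest(times, "expon", args=(0, 1 / 3)).pvalue > 1e-3

    def test_toy_fast_always_reaches_fixed_point(self):
        model, config = load_fixture("toy-fast", max_time=60.0, sample_count=200)
        for traj in run_ensemble(model, config, seed=3):
            assert traj.states[-1] == 0

    @given(st.integers(0, 15), st.integers(0, 3))
    def test_trajectory_invariants_on_random_models(self, model_seed, run_seed):
        model, config = load_fixture(
            "random-4-node", seed=model_seed, sample_count=1
        )
        traj = simulate_trajectory(model, config, rng(run_seed))
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[-1] <= config.max_time
        pairs = zip(traj.states[:-1], traj.states[1:])
        assert all(bin(int(a) ^ int(b)).count("1") == 1 for a, b in pairs)


class TestEnsemble:
    def test_reproducible_from_seed(self, toy_fast):
        model, config = toy_fast
        config.sample_count = 50
        a = run_ensemble(model, config, seed=9)
        b = run_ensemble(model, config, seed=9)
        assert all(
            np.array_equal(x.times, y.times) and np.array_equal(x.states, y.states)
            for x, y in zip(a, b)
        )

    def test_parallel_degree_does_not_change_results(self, toy_fast):
        model, config = toy_fast
        config.sample_count = 50
        a = run_ensemble(model, config, seed=9)
        config.parallel_degree = 4
        b = run_ensemble(model, config, seed=9)
        assert all(np.array_equal(x.states, y.states) for x, y in zip(a, b))

    def test_different_seeds_differ(self, toy_fast):
        model, config = toy_fast
        config.sample_count = 20
        a = run_ensemble(model, config, seed=1)
        b = run_ensemble(model, config, seed=2)
        assert any(
            not np.array_equal(x.times, y.times) for x, y in zip(a, b)
        )

    def test_singleton_ensemble(self, toy_fast):
        model, config = toy_fast
        config.sample_count = 1
        assert len(run_ensemble(model, config, seed=0)) == 1


class TestHoldingTimes:
    def test_mean_holding_time_is_inverse_total_rate(self, toy_fast):
        model, _ = toy_fast
        ts = transitions(model, 1 << model.index["C"])  # rho_tot = 11
        r = rng(21)
        n = 50_000
        dts = np.array([gillespie_step(ts, 1 - r.random(), 0.5)[0] for _ in range(n)])
        # Exponential(11): mean 1/11, sd 1/11 -> 4-sigma band
        assert abs(dts.mean() - 1 / 11) < 4 / (11 * math.sqrt(n))


class TestEmbeddedJumpChain:
    def test_equal_rates_reproduce_asynchronous_probabilities(self):
        """With all rates equal, jump targets are uniform over the gamma(S)
        asynchronous transitions out of S."""
        model, _ = load_fixture("toy-slow")
        model.parameters["escape"] = 1.0  # all rates equal
        state = 0b110  # [ABC]=[011]... gamma from transitions
        r = rng(17)
        for state in range(1, 8):
            ts = transitions(model, state)
            gamma = len(ts)
            if gamma < 2:
                continue
            n = 20_000
            counts = np.zeros(gamma)
            for _ in range(n):
                _, nxt = gillespie_step(ts, 0.5, 1 - r.random())
                counts[ts.targets.index(nxt)] += 1
            freq = counts / n
            se = math.sqrt((1 / gamma) * (1 - 1 / gamma) / n)
            assert np.all(np.abs(freq - 1 / gamma) < 5 * se)
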