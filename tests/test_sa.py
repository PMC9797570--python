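"""Simulated-annealing tests: schedule, moves, acceptance, convergence."""

import math

import numpy as np
import pytest

from gduplan.core import (
    GduScenario,
    InfeasibleInstanceError,
    Instance,
    PlantingSchedule,
    Population,
    evaluate_profile,
    objective_case1_stoch,
)
from gduplan.sa import SaConfig, accept, anneal, initial_solution, neighbor, temperature

from _helpers import brute_force_minimum, infeasible_instance, toy_stochastic_instance


class TestTemperature:
    def test_initial(self):
        assert temperature(0, SaConfig()) == 30_000.0

    def test_one_step(self):
        assert temperature(1, SaConfig()) == pytest.approx(29_850.0)

    def test_no_decay_at_alpha_one(self):
        cfg = SaConfig(alpha=1.0)
        assert temperature(500, cfg) == 30_000.0

    def test_strictly_decreasing(self):
        cfg = SaConfig()
        temps = [temperature(k, cfg) for k in range(100)]
        assert all(a > b for a, b in zip(temps, temps[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SaConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SaConfig(t0=0.0)


class _StubRng:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestAccept:
    def test_improving_always(self, rng):
        assert accept(10.0, 5.0, 1e-9 + 1.0, rng)
        assert accept(10.0, 10.0, 1.0, rng)

    def test_half_probability_at_t_ln2(self):
        T = 7.0
        e_new = 3.0 + T * math.log(2.0)
        assert accept(3.0, e_new, T, _StubRng(0.49))
        assert not accept(3.0, e_new, T, _StubRng(0.51))

    def test_vanishing_at_low_temperature(self):
        assert not accept(0.0, 10.0, 1e-6, _StubRng(1e-12))

    def test_literal_mode_always_accepts_worse(self, rng):
        # the sign-flipped exponent exceeds 1 for worsening moves
        for _ in range(20):
            assert accept(5.0, 50.0, 10.0, rng, mode="literal")

    def test_statistical_rate(self, rng):
        T, d = 10.0, 5.0
        target = math.exp(-d / T)
        hits = sum(accept(0.0, d, T, rng) for _ in range(4000))
        assert hits / 4000 == pytest.approx(target, abs=0.03)


class TestInitialSolution:
    def test_unique_when_windows_are_singletons(self):
        scen = GduScenario("s", [100.0] * 10)
        pops = [Population(i, i + 1, i + 1, 200.0, 50.0, 60.0) for i in range(3)]
        inst = Instance(pops, [scen], T=10, capacity=100.0)
        sched = initial_solution(inst, np.random.default_rng(0))
        assert sched.plant_week == {0: 1, 1: 2, 2: 3}

    def test_seed_determinism(self):
        inst = toy_stochastic_instance(2)
        a = initial_solution(inst, np.random.default_rng(7))
        b = initial_solution(inst, np.random.default_rng(7))
        assert a.plant_week == b.plant_week

    def test_always_valid_and_mature(self):
        inst = toy_stochastic_instance(3)
        for seed in range(10):
            sched = initial_solution(inst, np.random.default_rng(seed))
            sched.validate(inst)
            assert not evaluate_profile(sched, inst).unreached

    def test_infeasible_instance_names_populations(self):
        inst = infeasible_instance()
        with pytest.raises(InfeasibleInstanceError) as err:
            initial_solution(inst, np.random.default_rng(0))
        assert err.value.population_ids == [p.id for p in inst.populations]


class TestNeighbor:
    def _uniform_toy(self):
        scen = GduScenario("s", [100.0] * 10)
        pops = [
            Population(1, 2, 6, 250.0, 50.0, 60.0),   # smallest HQ
            Population(2, 2, 6, 250.0, 100.0, 120.0),
            Population(3, 2, 6, 250.0, 200.0, 220.0),
        ]
        return Instance(pops, [scen], T=10, capacity=350.0)

    def test_targets_smallest_hq_at_tallest_week(self):
        inst = self._uniform_toy()
        sched = PlantingSchedule({1: 3, 2: 3, 3: 3})  # all harvest together
        cfg = SaConfig(moves_per_max_week=1)
        new, noop = neighbor(sched, inst, np.random.default_rng(0), cfg)
        assert not noop
        assert new.plant_week[2] == 3 and new.plant_week[3] == 3
        assert new.plant_week[1] in {2, 4, 5}  # +/-1 or +/-2, clamped to window

    def test_single_population_shift_or_noop(self):
        scen = GduScenario("s", [100.0] * 10)
        inst = Instance(
            [Population(1, 3, 3, 200.0, 50.0, 60.0)], [scen], T=10, capacity=50.0
        )
        sched = PlantingSchedule({1: 3})
        new, noop = neighbor(sched, inst, np.random.default_rng(0), SaConfig())
        assert noop and new.plant_week == {1: 3}

    def test_result_always_window_valid(self):
        inst = toy_stochastic_instance(4, n=6, k=2, T=15)
        rng = np.random.default_rng(0)
        sched = initial_solution(inst, rng)
        cfg = SaConfig()
        for _ in range(50):
            sched, _ = neighbor(sched, inst, rng, cfg)
            sched.validate(inst)
            assert not evaluate_profile(sched, inst).unreached


class TestAnneal:
    def test_zero_iterations_returns_initial(self):
        inst = toy_stochastic_instance(1)
        cfg = SaConfig(k_max=0, seed=5)
        result, trace = anneal(inst, cfg)
        expected = initial_solution(inst, np.random.default_rng(5))
        assert result.schedule.plant_week == expected.plant_week
        assert len(trace.iteration) == 0

    def test_unique_schedule_exact_energy(self):
        scen = GduScenario("s", [100.0] * 10)
        pops = [Population(i, i + 1, i + 1, 200.0, 50.0, 60.0) for i in range(3)]
        inst = Instance(pops, [scen], T=10, capacity=50.0)
        result, _ = anneal(inst, SaConfig(k_max=20, seed=0))
        profile = evaluate_profile(result.schedule, inst)
        assert result.objective == objective_case1_stoch(profile, 50.0)

    def test_seed_determinism_trace(self):
        inst = toy_stochastic_instance(2)
        cfg = SaConfig(k_max=200, seed=9)
        r1, t1 = anneal(inst, cfg)
        r2, t2 = anneal(inst, cfg)
        assert r1.schedule.plant_week == r2.schedule.plant_week
        assert t1.current_energy == t2.current_energy
        assert t1.accepted == t2.accepted

    def test_best_energy_monotone(self):
        inst = toy_stochastic_instance(3)
        _, trace = anneal(inst, SaConfig(k_max=300, seed=1))
        best = trace.best_energy
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_reported_energy_is_reevaluation(self):
        inst = toy_stochastic_instance(4)
        result, _ = anneal(inst, SaConfig(k_max=300, seed=2))
        profile = evaluate_profile(result.schedule, inst)
        assert result.objective == objective_case1_stoch(profile, inst.capacity)

    def test_never_below_oracle_and_usually_optimal(self):
        inst = toy_stochastic_instance(1, n=6, k=2, T=15)
        oracle, _ = brute_force_minimum(inst, "case1_stoch")
        hits = 0
        for seed in range(10):
            result, _ = anneal(inst, SaConfig(k_max=2000, seed=seed))
            assert result.objective >= oracle - 1e-9
            hits += result.objective == pytest.approx(oracle, abs=1e-9)
        assert hits >= 8

    def test_case2_energy_and_lowest_capacity(self):
        inst = toy_stochastic_instance(5, n=5, k=2, T=15)
        cfg = SaConfig(k_max=500, seed=3, objective="case2_stoch")
        result, _ = anneal(inst, cfg)
        profile = evaluate_profile(result.schedule, inst)
        from gduplan.core import objective_case2_stoch

        assert result.objective == objective_case2_stoch(profile)
        active = profile.A_max[1:][profile.A_max[1:] > 0]
        assert result.extras["lowest_capacity"] == float(active.max())
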