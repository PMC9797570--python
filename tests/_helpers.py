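"""Shared test helpers: brute-force oracles and toy instance factories.

The oracles enumerate every window assignment and score it with the core
objective evaluators only — fully independent of the MILP and SA paths
they are used to check.
"""

from __future__ import annotations

import itertools

from gduplan.core import (
    Instance,
    PlantingSchedule,
    evaluate_profile,
    objective_case1_det,
    objective_case1_stoch,
    objective_case2_det,
    objective_case2_stoch,
)
from gduplan.synth import GeneratorConfig, generate_instance


def enumerate_schedules(instance: Instance):
    """Yield every window-respecting schedule (cartesian product)."""
    ids = [p.id for p in instance.populations]
    windows = [list(p.window) for p in instance.populations]
    for combo in itertools.product(*windows):
        yield PlantingSchedule(plant_week=dict(zip(ids, combo)))


def brute_force_minimum(instance: Instance, objective: str, all_weeks: bool = False):
    """Exhaustive minimum of an objective over all window assignments.

    Schedules under which any (population, scenario) pair fails to mature
    are excluded, matching the MILP feasible set.  Returns
    ``(best_value, best_schedule)`` or ``(None, None)``.
    """
    best_value, best_schedule = None, None
    for schedule in enumerate_schedules(instance):
        profile = evaluate_profile(schedule, instance)
        if profile.unreached:
            continue
        if objective == "case1_det":
            value = objective_case1_det(profile, instance.capacity)
        elif objective == "case1_stoch":
            value = objective_case1_stoch(profile, instance.capacity, all_weeks=all_weeks)
        elif objective == "case2_det":
            value = objective_case2_det(profile, instance.theta_w)
        elif objective == "case2_stoch":
            value = objective_case2_stoch(profile)
        else:
            raise ValueError(objective)
        if best_value is None or value < best_value:
            best_value, best_schedule = value, schedule
    return best_value, best_schedule


def toy_deterministic_instance(seed: int, n: int = 5, T: int = 18) -> Instance:
    """Small single-scenario instance (enumeration stays cheap)."""
    cfg = GeneratorConfig(
        n_populations=n, T=T, K=1, seed=seed,
        window_start_range=(2, max(2, T // 3)),
        window_width_range=(1, 3),
        required_gdu_range=(100.0, 450.0),
        climate_mean_peak=100.0, climate_amplitude=40.0, climate_noise_sd=10.0,
    )
    return generate_instance(cfg)


def toy_stochastic_instance(seed: int, n: int = 5, k: int = 2, T: int = 15) -> Instance:
    """Small multi-scenario instance for the stochastic oracle tests."""
    cfg = GeneratorConfig(
        n_populations=n, T=T, K=k, seed=seed,
        window_start_range=(2, max(2, T // 3)),
        window_width_range=(1, 3),
        required_gdu_range=(100.0, 400.0),
        climate_mean_peak=100.0, climate_amplitude=40.0, climate_noise_sd=12.0,
    )
    return generate_instance(cfg)


def infeasible_instance(seed: int = 0, n: int = 4, k: int = 2, T: int = 15) -> Instance:
    """Cold-site analogue: requirements unreachable under every scenario."""
    cfg = GeneratorConfig(
        n_populations=n, T=T, K=k, seed=seed,
        window_start_range=(2, 5), window_width_range=(1, 2),
        required_gdu_range=(50_000.0, 60_000.0),
        climate_mean_peak=100.0, climate_amplitude=40.0, climate_noise_sd=5.0,
    )
    return generate_instance(cfg, allow_infeasible=True)
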