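"""Single-scenario MILPs: fixed-capacity deviation and capacity-sizing minimax.

Both models share the scheduling core — one planting week per population
inside its window, one harvest week, and the earliest-harvest pair of
heat constraints — and differ only in the objective block:

* case 1 minimizes ``Σ_j (e⁺_j + e⁻_j)`` where
  ``w_j·C − Σ_i HQ_i·t^h_ij = e⁺_j − e⁻_j`` (absolute-deviation
  linearization);
* case 2 minimizes ``z + θ_w·Σ_j w_j`` with ``z ≥ Σ_i HQ_i·t^h_ij`` for
  every week (minimax linearization); ``z*`` is the lowest capacity.

Extracted schedules are always re-validated and re-scored by the core
evaluators, so solver numerics cannot leak into reported objectives.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..core import (
    GduScenario,
    InfeasibleInstanceError,
    Instance,
    PlantingSchedule,
    SolveResult,
    cumulative_gdu,
    evaluate_profile,
    harvest_week,
    objective_case1_det,
    objective_case2_det,
    UNREACHED,
)
from ..core.feasibility import feasibility_report
from .model import BINARY, CONTINUOUS, MilpModel, MilpSolution, solve_milp

__all__ = ["build_case1", "build_case2", "solve", "solve_case1", "solve_case2"]

#: Relative epsilon turning the strict earliest-harvest inequality into
#: ``<= G_min - eps`` (continuous GDUs; the integer-data form uses 1).
EPS_REL = 1e-6
EPS_FLOOR = 1e-4


def _earliest_eps(required_gdu: float) -> float:
    return max(EPS_REL * required_gdu, EPS_FLOOR)


def _single_scenario(instance: Instance, scenario: Optional[GduScenario]) -> GduScenario:
    if scenario is not None:
        return scenario
    if instance.K != 1:
        raise ValueError(
            f"deterministic build needs exactly one scenario; instance has K={instance.K}"
        )
    return instance.scenarios[0]


def _scenario_view(instance: Instance, scenario: GduScenario) -> Instance:
    """The instance restricted to a single scenario (for evaluation)."""
    return Instance(
        populations=instance.populations,
        scenarios=[scenario],
        T=instance.T,
        capacity=instance.capacity,
        theta_w=instance.theta_w,
        hq_case=instance.hq_case,
    )


def _check_maturity(instance: Instance, scenario: GduScenario) -> None:
    report = feasibility_report(_scenario_view(instance, scenario))
    if not report.feasible:
        raise InfeasibleInstanceError(report.offending_pairs)


def _candidate_harvest_weeks(
    instance: Instance, cum: np.ndarray, dense: bool
) -> dict[int, list[int]]:
    """Weeks where each population can possibly be harvested.

    Sparse mode keeps only weeks reachable via the earliest-harvest rule
    from some window week; this preserves the feasible set exactly.
    """
    out: dict[int, list[int]] = {}
    for p in instance.populations:
        if dense:
            out[p.id] = list(range(1, instance.T + 1))
            continue
        weeks = set()
        for j in p.window:
            h = harvest_week(j, p.required_gdu, cum)
            if h != UNREACHED:
                weeks.add(h)
        out[p.id] = sorted(weeks)
    return out


def _add_scheduling_core(
    model: MilpModel,
    instance: Instance,
    cum: np.ndarray,
    dense: bool,
) -> dict[int, list[int]]:
    """Add planting/harvest binaries and the shared constraint groups.

    Groups: ``one_planting`` (exactly one window week), ``one_harvest``,
    ``gdu_reach`` (accumulation meets the requirement by the harvest
    week) and ``gdu_earliest`` (the week before falls short, forcing the
    earliest reach).  The window restriction is structural: planting
    variables exist only for window weeks.
    """
    N, T = instance.N, instance.T
    candidates = _candidate_harvest_weeks(instance, cum, dense)
    for p in instance.populations:
        for j in p.window:
            model.add_variable(f"tp_{p.id}_{j}", BINARY, (p.id, j), group="plant")
        for j in candidates[p.id]:
            model.add_variable(f"th_{p.id}_{j}", BINARY, (p.id, j), group="harvest")
    for j in range(1, T + 1):
        model.add_variable(f"w_{j}", BINARY, (j,), group="week_indicator")

    for p in instance.populations:
        model.add_constraint(
            {f"tp_{p.id}_{j}": 1.0 for j in p.window}, "==", 1.0, "one_planting"
        )
        model.add_constraint(
            {f"th_{p.id}_{j}": 1.0 for j in candidates[p.id]}, "==", 1.0, "one_harvest"
        )
        eps = _earliest_eps(p.required_gdu)
        reach = {f"th_{p.id}_{j}": float(cum[j]) for j in candidates[p.id]}
        for j in p.window:
            reach[f"tp_{p.id}_{j}"] = -float(cum[j])
        model.add_constraint(reach, ">=", p.required_gdu, "gdu_reach")
        earliest = {f"th_{p.id}_{j}": float(cum[j - 1]) for j in candidates[p.id]}
        for j in p.window:
            earliest[f"tp_{p.id}_{j}"] = earliest.get(f"tp_{p.id}_{j}", 0.0) - float(cum[j])
        model.add_constraint(earliest, "<=", p.required_gdu - eps, "gdu_earliest")

    harvest_weeks = sorted({j for weeks in candidates.values() for j in weeks})
    for j in harvest_weeks:
        coeffs = {f"w_{j}": float(N)}
        for p in instance.populations:
            if j in candidates[p.id]:
                coeffs[f"th_{p.id}_{j}"] = -1.0
        model.add_constraint(coeffs, ">=", 0.0, "week_link")
    model.metadata["candidates"] = candidates
    return candidates


def build_case1(
    instance: Instance,
    scenario: Optional[GduScenario] = None,
    dense: bool = False,
) -> MilpModel:
    """Build the fixed-capacity deviation MILP for one GDU scenario.

    Raises :class:`InfeasibleInstanceError` before any solver call when
    some population cannot mature from any window week.
    """
    scenario = _single_scenario(instance, scenario)
    if instance.capacity is None:
        raise ValueError("case 1 requires a capacity")
    _check_maturity(instance, scenario)
    cum = cumulative_gdu(scenario)
    model = MilpModel(name="case1_det")
    candidates = _add_scheduling_core(model, instance, cum, dense)
    C = float(instance.capacity)
    for j in range(1, instance.T + 1):
        model.add_variable(f"ep_{j}", CONTINUOUS, (j,), group="dev_pos")
        model.add_variable(f"em_{j}", CONTINUOUS, (j,), group="dev_neg")
        coeffs = {f"w_{j}": C, f"ep_{j}": -1.0, f"em_{j}": 1.0}
        for p in instance.populations:
            if j in candidates[p.id]:
                coeffs[f"th_{p.id}_{j}"] = -float(instance.hq(p))
        model.add_constraint(coeffs, "==", 0.0, "capacity_dev")
    model.set_objective(
        {f"ep_{j}": 1.0 for j in range(1, instance.T + 1)}
        | {f"em_{j}": 1.0 for j in range(1, instance.T + 1)}
    )
    model.metadata.update({"case": 1, "scenario": scenario.label, "dense": dense})
    return model


def build_case2(
    instance: Instance,
    scenario: Optional[GduScenario] = None,
    dense: bool = False,
) -> MilpModel:
    """Build the capacity-sizing minimax MILP for one GDU scenario."""
    scenario = _single_scenario(instance, scenario)
    _check_maturity(instance, scenario)
    cum = cumulative_gdu(scenario)
    model = MilpModel(name="case2_det")
    candidates = _add_scheduling_core(model, instance, cum, dense)
    model.add_variable("z", CONTINUOUS, (), group="peak")
    harvest_weeks = sorted({j for weeks in candidates.values() for j in weeks})
    for j in harvest_weeks:
        coeffs = {"z": 1.0}
        for p in instance.populations:
            if j in candidates[p.id]:
                coeffs[f"th_{p.id}_{j}"] = -float(instance.hq(p))
        model.add_constraint(coeffs, ">=", 0.0, "peak_bound")
    obj = {"z": 1.0}
    for j in range(1, instance.T + 1):
        obj[f"w_{j}"] = float(instance.theta_w)
    model.set_objective(obj)
    model.metadata.update({"case": 2, "scenario": scenario.label, "dense": dense})
    return model


def solve(model: MilpModel, time_limit: float = 600.0, rel_gap: float = 0.0) -> MilpSolution:
    """Solve a built model with the HiGHS backend (thin wrapper)."""
    return solve_milp(model, time_limit=time_limit, rel_gap=rel_gap)


def _extract_schedule(solution: MilpSolution, instance: Instance) -> PlantingSchedule:
    plant: dict[int, int] = {}
    for p in instance.populations:
        chosen = [j for j in p.window if solution.values.get(f"tp_{p.id}_{j}", 0.0) > 0.5]
        if len(chosen) != 1:
            raise RuntimeError(
                f"population {p.id}: expected exactly one planting week, got {chosen}"
            )
        plant[p.id] = chosen[0]
    schedule = PlantingSchedule(plant_week=plant)
    schedule.validate(instance)
    return schedule


def _check_harvest_support(
    solution: MilpSolution, model: MilpModel, view: Instance, profile
) -> None:
    """Model t^h support must match independently recomputed harvest weeks."""
    label = view.scenarios[0].label
    candidates = model.metadata["candidates"]
    for p in view.populations:
        chosen = [
            j for j in candidates[p.id] if solution.values.get(f"th_{p.id}_{j}", 0.0) > 0.5
        ]
        recomputed = profile.harvest_week[(p.id, label)]
        if len(chosen) != 1 or chosen[0] != recomputed:
            raise RuntimeError(
                f"population {p.id}: model harvest {chosen} != recomputed {recomputed}"
            )


def _objective_consistent(solver_obj: float, recomputed: float) -> bool:
    return abs(solver_obj - recomputed) <= 1e-6 * max(1.0, abs(recomputed))


def solve_case1(
    instance: Instance,
    scenario: Optional[GduScenario] = None,
    time_limit: float = 600.0,
    rel_gap: float = 0.0,
) -> SolveResult:
    """Build, solve and re-validate the fixed-capacity deterministic model."""
    scenario = _single_scenario(instance, scenario)
    try:
        model = build_case1(instance, scenario)
    except InfeasibleInstanceError as err:
        return SolveResult(
            schedule=None, objective=None, status="infeasible",
            extras={"offending_pairs": err.pairs},
        )
    sol = solve(model, time_limit=time_limit, rel_gap=rel_gap)
    if sol.status in ("infeasible", "unbounded") or not sol.values:
        return SolveResult(schedule=None, objective=None, status=sol.status, gap=sol.gap)
    view = _scenario_view(instance, scenario)
    schedule = _extract_schedule(sol, view)
    profile = evaluate_profile(schedule, view)
    _check_harvest_support(sol, model, view, profile)
    objective = objective_case1_det(profile, view.capacity)
    if sol.status == "optimal" and not _objective_consistent(sol.objective, objective):
        raise RuntimeError(
            f"solver objective {sol.objective} inconsistent with recomputed {objective}"
        )
    return SolveResult(
        schedule=schedule, objective=objective, status=sol.status,
        profile=profile, harvest_week=profile.harvest_week, gap=sol.gap,
    )


#: Stopping gap convention for the capacity-sizing model.
CASE2_DEFAULT_REL_GAP = 0.001


def solve_case2(
    instance: Instance,
    scenario: Optional[GduScenario] = None,
    time_limit: float = 600.0,
    rel_gap: float = 0.0,
) -> SolveResult:
    """Build, solve and re-validate the capacity-sizing deterministic model.

    ``extras['lowest_capacity']`` carries the optimal peak weekly harvest
    (the lowest storage capacity required).
    """
    scenario = _single_scenario(instance, scenario)
    try:
        model = build_case2(instance, scenario)
    except InfeasibleInstanceError as err:
        return SolveResult(
            schedule=None, objective=None, status="infeasible",
            extras={"offending_pairs": err.pairs},
        )
    sol = solve(model, time_limit=time_limit, rel_gap=rel_gap)
    if sol.status in ("infeasible", "unbounded") or not sol.values:
        return SolveResult(schedule=None, objective=None, status=sol.status, gap=sol.gap)
    view = _scenario_view(instance, scenario)
    schedule = _extract_schedule(sol, view)
    profile = evaluate_profile(schedule, view)
    _check_harvest_support(sol, model, view, profile)
    objective = objective_case2_det(profile, view.theta_w)
    if sol.status == "optimal" and rel_gap == 0.0 and not _objective_consistent(
        sol.objective, objective
    ):
        raise RuntimeError(
            f"solver objective {sol.objective} inconsistent with recomputed {objective}"
        )
    lowest_capacity = float(profile.A[1:, 0].max()) if instance.N else 0.0
    return SolveResult(
        schedule=schedule, objective=objective, status=sol.status,
        profile=profile, harvest_week=profile.harvest_week, gap=sol.gap,
        extras={"lowest_capacity": lowest_capacity, "z": sol.values.get("z")},
    )
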