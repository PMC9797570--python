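"""Exact multi-scenario MILP with a shared planting schedule.

One set of planting binaries is shared across all GDU scenarios; each
scenario gets its own harvest binaries driven by the earliest-harvest
constraints under that scenario's cumulative heat.  The per-week maximum
harvest quantity across scenarios (the envelope) is linearized exactly
with selector binaries, and the objective is the absolute deviation of
the envelope from capacity over harvesting weeks (with an ``all_weeks``
variant covering every week of the horizon).

A dense "audit" mode instantiates the formulation's full variable set —
``N·K·T`` harvest binaries, ``N·T`` planting binaries, ``K·T``
per-scenario weekly indicators and ``T`` envelope variables — so the
model-size census can be checked against the closed-form count;
production mode sparsifies to window and reachable weeks.
"""

from __future__ import annotations

import numpy as np

from ..core import (
    InfeasibleInstanceError,
    Instance,
    PlantingSchedule,
    SolveResult,
    evaluate_profile,
    harvest_week,
    objective_case1_stoch,
    UNREACHED,
)
from ..core.feasibility import count_stochastic_milp_variables, feasibility_report
from .deterministic import _earliest_eps, _extract_schedule, _objective_consistent
from .model import BINARY, CONTINUOUS, MilpModel, MilpSolution, solve_milp

__all__ = [
    "build_stochastic_case1",
    "solve_stochastic_case1",
    "audit_variable_count",
    "dense_variable_census",
]


def build_stochastic_case1(
    instance: Instance,
    all_weeks: bool = False,
    audit_dense: bool = False,
) -> MilpModel:
    """Build the multi-scenario fixed-capacity MILP.

    Raises :class:`InfeasibleInstanceError` naming every offending
    (population, scenario) pair when some population cannot mature under
    some scenario from any window week.
    """
    if instance.capacity is None:
        raise ValueError("the stochastic fixed-capacity model requires a capacity")
    report = feasibility_report(instance)
    if not report.feasible:
        raise InfeasibleInstanceError(report.offending_pairs)

    N, K, T = instance.N, instance.K, instance.T
    C = float(instance.capacity)
    cum = instance.cumulative()
    big_m = max(instance.total_hq(), 1.0)

    model = MilpModel(name="case1_stoch")
    # Per-(population, scenario) candidate harvest weeks.
    candidates: dict[tuple[int, int], list[int]] = {}
    for p in instance.populations:
        for k in range(K):
            if audit_dense:
                candidates[(p.id, k)] = list(range(1, T + 1))
            else:
                weeks = set()
                for j in p.window:
                    h = harvest_week(j, p.required_gdu, cum[k])
                    if h != UNREACHED:
                        weeks.add(h)
                candidates[(p.id, k)] = sorted(weeks)

    # --- decision variables -----------------------------------------
    for p in instance.populations:
        plant_weeks = range(1, T + 1) if audit_dense else p.window
        for j in plant_weeks:
            in_window = p.earliest_plant_week <= j <= p.latest_plant_week
            model.add_variable(
                f"tp_{p.id}_{j}", BINARY, (p.id, j), group="plant",
                ub=None if in_window else 0.0,  # structural window restriction
            )
    for p in instance.populations:
        for k in range(K):
            for j in candidates[(p.id, k)]:
                model.add_variable(
                    f"th_{p.id}_{j}_{k}", BINARY, (p.id, j, k), group="harvest"
                )
    if audit_dense:
        for k in range(K):
            for j in range(1, T + 1):
                model.add_variable(
                    f"wk_{k}_{j}", BINARY, (k, j), group="scenario_week"
                )
    for j in range(1, T + 1):
        model.add_variable(f"amax_{j}", CONTINUOUS, (j,), group="envelope")

    # Linearization auxiliaries (outside the formulation's stated
    # decision-variable census).
    for j in range(1, T + 1):
        if not all_weeks:
            model.add_variable(f"w_{j}", BINARY, (j,), group="active_week", aux=True)
        for k in range(K):
            model.add_variable(f"y_{j}_{k}", BINARY, (j, k), group="env_pick", aux=True)
        model.add_variable(f"dp_{j}", CONTINUOUS, (j,), group="dev_pos", aux=True)
        model.add_variable(f"dm_{j}", CONTINUOUS, (j,), group="dev_neg", aux=True)

    # --- constraints -------------------------------------------------
    for p in instance.populations:
        model.add_constraint(
            {f"tp_{p.id}_{j}": 1.0 for j in p.window}, "==", 1.0, "one_planting"
        )
        for k in range(K):
            cand = candidates[(p.id, k)]
            model.add_constraint(
                {f"th_{p.id}_{j}_{k}": 1.0 for j in cand}, "==", 1.0, "one_harvest"
            )
            eps = _earliest_eps(p.required_gdu)
            reach = {f"th_{p.id}_{j}_{k}": float(cum[k, j]) for j in cand}
            for j in p.window:
                reach[f"tp_{p.id}_{j}"] = -float(cum[k, j])
            model.add_constraint(reach, ">=", p.required_gdu, "gdu_reach")
            earliest = {f"th_{p.id}_{j}_{k}": float(cum[k, j - 1]) for j in cand}
            for j in p.window:
                earliest[f"tp_{p.id}_{j}"] = (
                    earliest.get(f"tp_{p.id}_{j}", 0.0) - float(cum[k, j])
                )
            model.add_constraint(earliest, "<=", p.required_gdu - eps, "gdu_earliest")

    hq = {p.id: float(instance.hq(p)) for p in instance.populations}
    for j in range(1, T + 1):
        for k in range(K):
            present = [p.id for p in instance.populations if j in candidates[(p.id, k)]]
            # envelope >= each scenario's weekly quantity
            if present:
                lb = {f"amax_{j}": 1.0}
                for i in present:
                    lb[f"th_{i}_{j}_{k}"] = -hq[i]
                model.add_constraint(lb, ">=", 0.0, "envelope_lb")
            # tightness: envelope <= selected scenario's quantity
            ub = {f"amax_{j}": 1.0, f"y_{j}_{k}": big_m}
            for i in present:
                ub[f"th_{i}_{j}_{k}"] = -hq[i]
            model.add_constraint(ub, "<=", big_m, "envelope_ub")
            if audit_dense and present:
                link = {f"wk_{k}_{j}": float(N)}
                for i in present:
                    link[f"th_{i}_{j}_{k}"] = -1.0
                model.add_constraint(link, ">=", 0.0, "scenario_week_link")
            if not all_weeks and present:
                wlink = {f"w_{j}": float(N)}
                for i in present:
                    wlink[f"th_{i}_{j}_{k}"] = -1.0
                model.add_constraint(wlink, ">=", 0.0, "week_link")
        model.add_constraint(
            {f"y_{j}_{k}": 1.0 for k in range(K)}, "==", 1.0, "env_pick_one"
        )
        dev = {f"amax_{j}": -1.0, f"dp_{j}": -1.0, f"dm_{j}": 1.0}
        if all_weeks:
            model.add_constraint(dev, "==", -C, "capacity_dev")
        else:
            dev[f"w_{j}"] = C
            model.add_constraint(dev, "==", 0.0, "capacity_dev")

    model.set_objective(
        {f"dp_{j}": 1.0 for j in range(1, T + 1)}
        | {f"dm_{j}": 1.0 for j in range(1, T + 1)}
    )
    model.metadata.update(
        {"case": "1_stoch", "all_weeks": all_weeks, "audit_dense": audit_dense,
         "candidates": candidates}
    )
    return model


def audit_variable_count(model: MilpModel) -> int:
    """Census of the formulation's decision variables in a dense build.

    Counts planting, per-scenario harvest, per-scenario weekly-indicator
    and envelope variables (linearization auxiliaries excluded); equals
    :func:`~gduplan.core.feasibility.count_stochastic_milp_variables`.
    """
    if not model.metadata.get("audit_dense"):
        raise ValueError("audit census requires a model built with audit_dense=True")
    return sum(model.census(include_aux=False).values())


def dense_variable_census(N: int, K: int, T: int) -> dict[str, int]:
    """Enumerate the dense formulation's variable index sets and count them.

    An independent structural census (actual enumeration, not the closed
    form): harvest binaries over populations × scenarios × weeks,
    planting binaries over populations × weeks, weekly indicators over
    scenarios × weeks, and one envelope variable per week.
    """
    if min(N, K, T) < 1:
        raise ValueError("N, K, T must be positive integers")
    harvest = sum(1 for _ in range(N) for _ in range(K) for _ in range(T))
    plant = sum(1 for _ in range(N) for _ in range(T))
    scenario_week = sum(1 for _ in range(K) for _ in range(T))
    envelope = sum(1 for _ in range(T))
    return {
        "harvest": harvest,
        "plant": plant,
        "scenario_week": scenario_week,
        "envelope": envelope,
        "total": harvest + plant + scenario_week + envelope,
    }


def solve_stochastic_case1(
    instance: Instance,
    all_weeks: bool = False,
    time_limit: float = 600.0,
    rel_gap: float = 0.0,
) -> SolveResult:
    """Build, solve and re-validate the multi-scenario model.

    The returned objective is recomputed by
    :func:`~gduplan.core.objectives.objective_case1_stoch` from the
    extracted schedule, never read off the solver.
    """
    try:
        model = build_stochastic_case1(instance, all_weeks=all_weeks)
    except InfeasibleInstanceError as err:
        return SolveResult(
            schedule=None, objective=None, status="infeasible",
            extras={"offending_pairs": err.pairs,
                    "offending_populations": err.population_ids},
        )
    sol = solve_milp(model, time_limit=time_limit, rel_gap=rel_gap)
    if sol.status in ("infeasible", "unbounded") or not sol.values:
        return SolveResult(schedule=None, objective=None, status=sol.status, gap=sol.gap)
    schedule = _extract_schedule(sol, instance)
    profile = evaluate_profile(schedule, instance)
    # Shared-planting contract: the model's per-scenario harvest support
    # must match the independent earliest-harvest recomputation.
    for p in instance.populations:
        for k, s in enumerate(instance.scenarios):
            cand = model.metadata["candidates"][(p.id, k)]
            chosen = [
                j for j in cand if sol.values.get(f"th_{p.id}_{j}_{k}", 0.0) > 0.5
            ]
            recomputed = profile.harvest_week[(p.id, s.label)]
            if len(chosen) != 1 or chosen[0] != recomputed:
                raise RuntimeError(
                    f"population {p.id}, scenario {s.label}: model harvest "
                    f"{chosen} != recomputed {recomputed}"
                )
    # Envelope correctness on active weeks.
    for j in profile.active_weeks():
        if abs(sol.values[f"amax_{j}"] - profile.A_max[j]) > 1e-6 * max(
            1.0, profile.A_max[j]
        ):
            raise RuntimeError(
                f"week {j}: model envelope {sol.values[f'amax_{j}']} != "
                f"recomputed {profile.A_max[j]}"
            )
    objective = objective_case1_stoch(profile, instance.capacity, all_weeks=all_weeks)
    if sol.status == "optimal" and not _objective_consistent(sol.objective, objective):
        raise RuntimeError(
            f"solver objective {sol.objective} inconsistent with recomputed {objective}"
        )
    return SolveResult(
        schedule=schedule, objective=objective, status=sol.status,
        profile=profile, harvest_week=profile.harvest_week, gap=sol.gap,
    )
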