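"""Simulated annealing for the multi-scenario scheduling problem.

Geometric cooling, Metropolis acceptance and a problem-specific neighbor
move: at the tallest week of the cross-scenario harvest envelope, the
few smallest-quantity populations get their planting weeks nudged one or
two weeks; at the shortest active week, one population is pulled in from
the closest taller week.  Only planting weeks are decision variables —
harvest weeks follow from the earliest-harvest rule per scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    HarvestProfile,
    InfeasibleInstanceError,
    Instance,
    PlantingSchedule,
    SolveResult,
    UNREACHED,
    evaluate_profile,
    harvest_week,
    objective_case1_stoch,
    objective_case2_stoch,
)
from .core.feasibility import feasible_plant_weeks

__all__ = [
    "SaConfig",
    "SaTrace",
    "temperature",
    "initial_solution",
    "neighbor",
    "accept",
    "anneal",
]


@dataclass(frozen=True)
class SaConfig:
    """Annealing parameters (defaults follow the published schedule)."""

    t0: float = 30_000.0
    alpha: float = 0.995
    k_max: int = 700
    moves_per_max_week: int = 3
    shift_range: tuple[int, ...] = (1, 2)
    explore_prob: float = 0.2
    seed: int = 0
    objective: str = "case1_stoch"  # or "case2_stoch"
    acceptance: str = "metropolis"  # or "literal"
    all_weeks: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if not (0.0 <= self.explore_prob <= 1.0):
            raise ValueError("explore_prob must lie in [0, 1]")
        if self.objective not in ("case1_stoch", "case2_stoch"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.acceptance not in ("metropolis", "literal"):
            raise ValueError(f"unknown acceptance {self.acceptance!r}")


@dataclass
class SaTrace:
    """Per-iteration annealing record."""

    iteration: list[int] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    current_energy: list[float] = field(default_factory=list)
    best_energy: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    noop: list[bool] = field(default_factory=list)

    def append(self, k, temp, current, best, accepted, noop) -> None:
        self.iteration.append(k)
        self.temperature.append(temp)
        self.current_energy.append(current)
        self.best_energy.append(best)
        self.accepted.append(accepted)
        self.noop.append(noop)


def temperature(k: int, cfg: SaConfig) -> float:
    """Geometric cooling: ``T0 · alpha^k``."""
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    return cfg.t0 * cfg.alpha**k


class _Evaluator:
    """Cached per-population lookup tables for fast energy evaluation.

    For every population and every all-scenario-feasible planting week,
    the harvest week under each scenario is precomputed once.
    """

    def __init__(self, instance: Instance):
        self.instance = instance
        self.cum = instance.cumulative()
        self.feasible_weeks = feasible_plant_weeks(instance)
        infeasible = [i for i, weeks in self.feasible_weeks.items() if not weeks]
        if infeasible:
            pairs = []
            for p in instance.populations:
                if p.id in infeasible:
                    for k, s in enumerate(instance.scenarios):
                        if (
                            self.cum[k, instance.T]
                            - self.cum[k, p.earliest_plant_week]
                            < p.required_gdu
                        ):
                            pairs.append((p.id, s.label))
            raise InfeasibleInstanceError(pairs)
        self.hq = {p.id: float(instance.hq(p)) for p in instance.populations}
        # harvest[(pop_id, plant_week)][k] -> harvest week
        self.harvest: dict[tuple[int, int], tuple[int, ...]] = {}
        for p in instance.populations:
            for j in self.feasible_weeks[p.id]:
                self.harvest[(p.id, j)] = tuple(
                    harvest_week(j, p.required_gdu, self.cum[k])
                    for k in range(instance.K)
                )

    def weekly_matrix(self, plant: dict[int, int]) -> np.ndarray:
        """Harvest-quantity matrix ``A`` of shape ``(T+1, K)``."""
        A = np.zeros((self.instance.T + 1, self.instance.K))
        for i, j in plant.items():
            hw = self.harvest[(i, j)]
            q = self.hq[i]
            for k, h in enumerate(hw):
                A[h, k] += q
        return A

    def energy(self, plant: dict[int, int], cfg: SaConfig) -> float:
        A = self.weekly_matrix(plant)
        am = A.max(axis=1)[1:]
        if cfg.objective == "case1_stoch":
            if self.instance.capacity is None:
                raise ValueError("case1_stoch energy requires a capacity")
            C = self.instance.capacity
            if cfg.all_weeks:
                return float(np.abs(C - am).sum())
            return float(np.abs(C - am[am > 0]).sum())
        vals = am[am > 0]
        if vals.size <= 1:
            return 0.0
        return float(np.abs(np.diff(vals)).sum())


def initial_solution(instance: Instance, rng: np.random.Generator) -> PlantingSchedule:
    """Random schedule, uniform over each population's feasible window weeks.

    Feasible means the planting week lets the population mature under
    *every* scenario.  Raises :class:`InfeasibleInstanceError` naming the
    populations for which no such week exists.
    """
    ev = _Evaluator(instance)
    plant = {
        p.id: int(rng.choice(ev.feasible_weeks[p.id])) for p in instance.populations
    }
    return PlantingSchedule(plant_week=plant)


def accept(
    e_current: float,
    e_new: float,
    temp: float,
    rng: np.random.Generator,
    mode: str = "metropolis",
) -> bool:
    """Metropolis acceptance: improving moves always, worsening moves with
    probability ``exp(-(e_new - e_current)/temp)``.

    ``mode='literal'`` flips the exponent sign (which degenerates to
    always accepting worsening moves); kept for comparison only.
    """
    if temp <= 0:
        raise ValueError("temperature must be > 0")
    if e_new <= e_current:
        return True
    if mode == "metropolis":
        p = math.exp(-(e_new - e_current) / temp)
    elif mode == "literal":
        p = min(1.0, math.exp(-(e_current - e_new) / temp))
    else:
        raise ValueError(f"unknown acceptance mode {mode!r}")
    return bool(rng.random() < p)


def _argmax_scenario(A: np.ndarray, j: int) -> int:
    """Scenario attaining the envelope at week ``j`` (earliest tie)."""
    return int(np.argmax(A[j]))


def neighbor(
    schedule: PlantingSchedule,
    instance: Instance,
    rng: np.random.Generator,
    cfg: SaConfig,
    evaluator: Optional[_Evaluator] = None,
) -> tuple[PlantingSchedule, bool]:
    """One neighborhood move; returns ``(new_schedule, was_noop)``.

    Move (a): at the active week with the tallest envelope, shift the
    planting week of up to ``moves_per_max_week`` populations with the
    smallest harvest quantities by ±1 or ±2 weeks (uniform over feasible
    shifts; skipped when none is feasible).  Move (b): for the active
    week with the shortest envelope, re-plant one population from the
    closest taller week (ties broken toward earlier weeks, then smaller
    id) so that it lands on the short week under the scenario attaining
    that week's envelope value.

    With probability ``cfg.explore_prob`` a pure exploration move is made
    instead — one uniformly chosen population re-planted at a uniformly
    chosen feasible week; the directed moves alone form near-deterministic
    orbits that can trap the chain on small instances.
    """
    ev = evaluator if evaluator is not None else _Evaluator(instance)
    plant = dict(schedule.plant_week)

    if cfg.explore_prob > 0 and rng.random() < cfg.explore_prob:
        p = instance.populations[int(rng.integers(instance.N))]
        weeks = ev.feasible_weeks[p.id]
        j_new = int(weeks[int(rng.integers(len(weeks)))])
        changed = j_new != plant[p.id]
        plant[p.id] = j_new
        return PlantingSchedule(plant_week=plant), not changed

    A = ev.weekly_matrix(plant)
    am = A.max(axis=1)
    active = np.nonzero(am[1:] > 0)[0] + 1
    if active.size == 0:
        return PlantingSchedule(plant_week=plant), True

    changed = False

    # --- move (a): thin out the tallest week ------------------------
    j_top = int(active[np.argmax(am[active])])
    k_top = _argmax_scenario(A, j_top)
    at_top = [
        p for p in instance.populations
        if ev.harvest[(p.id, plant[p.id])][k_top] == j_top
    ]
    at_top.sort(key=lambda p: (ev.hq[p.id], p.id))
    deltas = [d for s in cfg.shift_range for d in (-s, s)]
    for p in at_top[: cfg.moves_per_max_week]:
        feas = set(ev.feasible_weeks[p.id])
        options = [plant[p.id] + d for d in deltas if plant[p.id] + d in feas]
        if not options:
            continue
        plant[p.id] = int(options[int(rng.integers(len(options)))])
        changed = True

    # --- move (b): fill the shortest active week --------------------
    if active.size >= 2:
        j_min = int(active[np.argmin(am[active])])
        if j_min != j_top:
            k_min = _argmax_scenario(A, j_min)
            donors = [
                int(j) for j in active if j != j_min and am[j] > am[j_min]
            ]
            donors.sort(key=lambda j: (abs(j - j_min), j))
            moved = False
            for j_from in donors:
                for p in sorted(instance.populations, key=lambda q: q.id):
                    if ev.harvest[(p.id, plant[p.id])][k_min] != j_from:
                        continue
                    for j_new in ev.feasible_weeks[p.id]:
                        if ev.harvest[(p.id, j_new)][k_min] == j_min:
                            plant[p.id] = j_new
                            moved = changed = True
                            break
                    if moved:
                        break
                if moved:
                    break

    # Ergodicity fallback: when neither directed component can change the
    # schedule (small instances freeze otherwise), re-plant one uniformly
    # chosen population at a uniformly chosen feasible week.
    if not changed:
        p = instance.populations[int(rng.integers(instance.N))]
        weeks = ev.feasible_weeks[p.id]
        j_new = int(weeks[int(rng.integers(len(weeks)))])
        if j_new != plant[p.id]:
            plant[p.id] = j_new
            changed = True

    return PlantingSchedule(plant_week=plant), not changed


def anneal(instance: Instance, cfg: SaConfig) -> tuple[SolveResult, SaTrace]:
    """Run the annealing loop and return the best schedule found.

    Fully reproducible under ``cfg.seed``; the reported objective is the
    core re-evaluation of the returned schedule, exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(instance)
    current = initial_solution(instance, rng)
    e_current = ev.energy(current.plant_week, cfg)
    best, e_best = current, e_current
    trace = SaTrace()
    for k in range(cfg.k_max):
        temp = temperature(k, cfg)
        candidate, noop = neighbor(current, instance, rng, cfg, evaluator=ev)
        e_new = ev.energy(candidate.plant_week, cfg)
        accepted = accept(e_current, e_new, temp, rng, mode=cfg.acceptance)
        if accepted:
            current, e_current = candidate, e_new
        if e_current < e_best:
            best, e_best = current, e_current
        trace.append(k, temp, e_current, e_best, accepted, noop)

    best.validate(instance)
    profile = evaluate_profile(best, instance)
    if cfg.objective == "case1_stoch":
        objective = objective_case1_stoch(
            profile, instance.capacity, all_weeks=cfg.all_weeks
        )
    else:
        objective = objective_case2_stoch(profile)
    assert objective == e_best, "energy bookkeeping diverged from re-evaluation"
    extras = {}
    if cfg.objective == "case2_stoch":
        active = profile.A_max[1:][profile.A_max[1:] > 0]
        extras["lowest_capacity"] = float(active.max()) if active.size else 0.0
    return (
        SolveResult(
            schedule=best, objective=objective, status="feasible",
            profile=profile, harvest_week=profile.harvest_week, extras=extras,
        ),
        trace,
    )
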