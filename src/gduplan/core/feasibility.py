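"""Maturity feasibility diagnostics and the stochastic model-size census."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Instance

__all__ = [
    "FeasibilityReport",
    "feasibility_report",
    "feasible_plant_weeks",
    "count_stochastic_milp_variables",
]


@dataclass
class FeasibilityReport:
    """Per-(population, scenario) maturity flags for an instance.

    ``reachable[(pop_id, scenario_label)]`` is True when at least one
    window week lets the population accumulate its required GDU within
    the horizon.  The instance is feasible only when every pair is
    reachable (a single shared planting schedule must work under every
    scenario).
    """

    feasible: bool
    reachable: dict[tuple[int, str], bool]
    offending_pairs: list[tuple[int, str]] = field(default_factory=list)

    @property
    def offending_populations(self) -> list[int]:
        return sorted({i for i, _ in self.offending_pairs})


def feasibility_report(instance: Instance) -> FeasibilityReport:
    """Check every (population, scenario) pair for maturity reachability.

    Because cumulative GDU is non-decreasing, planting earlier can only
    increase post-planting accumulation; a pair is reachable iff it is
    reachable when planted at the earliest window week.
    """
    cum = instance.cumulative()
    reachable: dict[tuple[int, str], bool] = {}
    offending: list[tuple[int, str]] = []
    for p in instance.populations:
        for k, s in enumerate(instance.scenarios):
            ok = cum[k, instance.T] - cum[k, p.earliest_plant_week] >= p.required_gdu
            reachable[(p.id, s.label)] = bool(ok)
            if not ok:
                offending.append((p.id, s.label))
    return FeasibilityReport(
        feasible=not offending, reachable=reachable, offending_pairs=offending
    )


def feasible_plant_weeks(instance: Instance) -> dict[int, list[int]]:
    """Window weeks from which every scenario reaches maturity, per population.

    For each scenario the reachable planting weeks form a prefix of the
    window (monotonicity), so the all-scenario intersection is itself a
    prefix — empty exactly when some single scenario is unreachable even
    at the earliest week.
    """
    cum = instance.cumulative()
    out: dict[int, list[int]] = {}
    for p in instance.populations:
        weeks = []
        for j in p.window:
            if all(
                cum[k, instance.T] - cum[k, j] >= p.required_gdu
                for k in range(instance.K)
            ):
                weeks.append(j)
        out[p.id] = weeks
    return out


def count_stochastic_milp_variables(N: int, K: int, T: int) -> int:
    """Decision-variable count of the dense multi-scenario MILP.

    ``N·K·T`` per-scenario harvest binaries, ``N·T`` planting binaries,
    ``K·T`` per-scenario weekly indicators and ``T`` envelope variables.
    """
    if min(N, K, T) < 1:
        raise ValueError("N, K, T must be positive integers")
    return N * K * T + N * T + K * T + T
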