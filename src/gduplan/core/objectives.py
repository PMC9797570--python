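"""Profile evaluation and the four scheduling objectives.

All objectives are pure functions of a :class:`~gduplan.core.types.HarvestProfile`
so that solver outputs can always be re-scored independently of the
solver that produced them.
"""

from __future__ import annotations

import numpy as np

from .gdu import harvest_week
from .types import HarvestProfile, Instance, PlantingSchedule, UNREACHED

__all__ = [
    "evaluate_profile",
    "objective_case1_det",
    "objective_case1_stoch",
    "objective_case2_det",
    "objective_case2_stoch",
]


def evaluate_profile(schedule: PlantingSchedule, instance: Instance) -> HarvestProfile:
    """Derive harvest weeks and weekly harvest quantities from a schedule.

    For every (population, scenario) pair the earliest-harvest rule is
    applied to the scenario's cumulative GDU.  Populations that never
    reach their requirement are listed in ``unreached`` (never silently
    dropped) and contribute nothing to ``A``.
    """
    schedule.validate(instance)
    T, K = instance.T, instance.K
    cum = instance.cumulative()
    A = np.zeros((T + 1, K))
    w = np.zeros((T + 1, K), dtype=bool)
    hw: dict[tuple[int, str], int | str] = {}
    unreached: list[tuple[int, str]] = []
    for p in instance.populations:
        pw = schedule.plant_week[p.id]
        hq = instance.hq(p)
        for k, s in enumerate(instance.scenarios):
            h = harvest_week(pw, p.required_gdu, cum[k])
            hw[(p.id, s.label)] = h
            if h == UNREACHED:
                unreached.append((p.id, s.label))
            else:
                A[h, k] += hq
                w[h, k] = True
    A_max = A.max(axis=1)
    return HarvestProfile(A=A, A_max=A_max, w=w, harvest_week=hw, unreached=unreached)


def _single_scenario_column(profile: HarvestProfile) -> np.ndarray:
    if profile.K != 1:
        raise ValueError(
            f"single-scenario profile required, got K={profile.K} scenarios"
        )
    return profile.A[1:, 0]


def objective_case1_det(profile: HarvestProfile, capacity: float) -> float:
    """Sum over harvesting weeks of |capacity − weekly harvest quantity|.

    The week indicator is 1 exactly on weeks with positive harvest, so
    empty weeks contribute nothing.  Equals the optimal ``Σ(e⁺+e⁻)`` of
    the linearized deterministic model at the same schedule.
    """
    a = _single_scenario_column(profile)
    active = a > 0
    return float(np.abs(capacity - a[active]).sum())


def objective_case1_stoch(
    profile: HarvestProfile, capacity: float, all_weeks: bool = False
) -> float:
    """Deviation of the per-week max envelope from capacity.

    Default: sum of ``|C − A_max[j]|`` over weeks with a positive
    envelope.  ``all_weeks=True`` reproduces the literal sum over all
    ``T`` weeks, where every empty week contributes ``C``.
    """
    am = profile.A_max[1:]
    if all_weeks:
        return float(np.abs(capacity - am).sum())
    active = am > 0
    return float(np.abs(capacity - am[active]).sum())


def objective_case2_det(profile: HarvestProfile, theta_w: float = 1.0) -> float:
    """Peak weekly harvest plus ``theta_w`` per harvesting week (minimax)."""
    a = _single_scenario_column(profile)
    active = a > 0
    if not active.any():
        return 0.0
    return float(a.max() + theta_w * active.sum())


def objective_case2_stoch(profile: HarvestProfile) -> float:
    """Total variation of the max envelope over its active weeks.

    With active weeks ``j_1 < … < j_m`` this is
    ``Σ_r |A_max[j_r] − A_max[j_{r+1}]|``: zero iff the envelope is
    constant across harvesting weeks, i.e. perfectly consistent.
    """
    am = profile.A_max[1:]
    vals = am[am > 0]
    if vals.size <= 1:
        return 0.0
    return float(np.abs(np.diff(vals)).sum())
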