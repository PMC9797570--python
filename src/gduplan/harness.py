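"""Head-to-head comparison of the heuristic and the exact stochastic MILP.

Mirrors the reduced-size evaluation protocol: both methods run on the
same instance, and every reported objective is recomputed from the
returned schedule by the core evaluators — never trusted from a solver.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .core import Instance, evaluate_profile, objective_case1_stoch
from .milp.stochastic import solve_stochastic_case1
from .sa import SaConfig, anneal

__all__ = ["evaluate_harness"]


def evaluate_harness(
    instance: Instance,
    sa_seeds: Sequence[int] = (0,),
    sa_config: Optional[SaConfig] = None,
    milp_time_limit: float = 600.0,
    all_weeks: bool = False,
) -> list[dict]:
    """Run SA (one row per seed) and the stochastic MILP on ``instance``.

    Returns a list of rows ``{method, seed, status, objective, gap}``.
    A MILP timeout is reported as ``time_limit`` with the incumbent's
    recomputed objective when one exists.
    """
    rows: list[dict] = []
    base = sa_config if sa_config is not None else SaConfig()
    for seed in sa_seeds:
        cfg = SaConfig(
            t0=base.t0, alpha=base.alpha, k_max=base.k_max,
            moves_per_max_week=base.moves_per_max_week,
            shift_range=base.shift_range, seed=seed,
            objective=base.objective, acceptance=base.acceptance,
            all_weeks=all_weeks,
        )
        result, _ = anneal(instance, cfg)
        profile = evaluate_profile(result.schedule, instance)
        objective = objective_case1_stoch(profile, instance.capacity, all_weeks=all_weeks)
        rows.append(
            {"method": "sa", "seed": seed, "status": result.status,
             "objective": objective, "gap": None}
        )
    milp = solve_stochastic_case1(
        instance, all_weeks=all_weeks, time_limit=milp_time_limit
    )
    objective = None
    if milp.schedule is not None:
        profile = evaluate_profile(milp.schedule, instance)
        objective = objective_case1_stoch(profile, instance.capacity, all_weeks=all_weeks)
    rows.append(
        {"method": "milp", "seed": None, "status": milp.status,
         "objective": objective, "gap": milp.gap}
    )
    return rows
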