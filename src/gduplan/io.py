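"""CSV readers/writers for instances, schedules and weekly reports.

All weeks in files are 1-based integers; no dates appear in outputs.
Readers validate the domain invariants and fail with row-numbered
messages.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    GduScenario,
    HarvestProfile,
    Instance,
    PlantingSchedule,
    Population,
    SolveResult,
    UNREACHED,
    evaluate_profile,
    extend_weekly,
)

__all__ = [
    "read_populations",
    "write_populations",
    "read_gdu_weekly",
    "write_gdu_weekly",
    "read_temps_daily",
    "write_schedule",
    "read_schedule",
    "report_weekly",
]

POPULATION_COLUMNS = ["id", "early_week", "late_week", "required_gdu", "hq_case1", "hq_case2"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_populations(path) -> list[Population]:
    """Read a population table (columns: id, early_week, late_week,
    required_gdu, hq_case1, hq_case2)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, POPULATION_COLUMNS, path)
    pops = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pops.append(
                Population(
                    id=int(row.id),
                    earliest_plant_week=int(row.early_week),
                    latest_plant_week=int(row.late_week),
                    required_gdu=float(row.required_gdu),
                    hq_case1=float(row.hq_case1),
                    hq_case2=float(row.hq_case2),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {row_no}: {err}") from err
    ids = [p.id for p in pops]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate population ids")
    return pops


def write_populations(populations: list[Population], path) -> None:
    pd.DataFrame(
        [
            {
                "id": p.id,
                "early_week": p.earliest_plant_week,
                "late_week": p.latest_plant_week,
                "required_gdu": p.required_gdu,
                "hq_case1": p.hq_case1,
                "hq_case2": p.hq_case2,
            }
            for p in populations
        ]
    ).to_csv(path, index=False)


def read_gdu_weekly(
    path, T: Optional[int] = None, extend: str = "wrap"
) -> list[GduScenario]:
    """Read long-format weekly GDU series (columns: scenario, week, gdu).

    Each scenario must cover contiguous weeks ``1..L``.  When ``T`` is
    given, series are truncated or extended to length ``T`` with the
    chosen extension mode (``wrap`` repeats the same series from week 1).
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["scenario", "week", "gdu"], path)
    scenarios = []
    for label, grp in df.groupby("scenario", sort=False):
        grp = grp.sort_values("week")
        weeks = grp["week"].to_numpy()
        if not np.array_equal(weeks, np.arange(1, len(weeks) + 1)):
            first_bad = int(grp.index[0]) + 2
            raise ValueError(
                f"{path}: scenario {label!r} (first row {first_bad}): weeks must be "
                f"contiguous 1..L, got {weeks.tolist()[:5]}..."
            )
        values = grp["gdu"].astype(float).tolist()
        if T is not None:
            values = extend_weekly(values, T, mode=extend)
        scenarios.append(GduScenario(label=str(label), weekly_gdu=values))
    if not scenarios:
        raise ValueError(f"{path}: no scenarios found")
    return scenarios


def write_gdu_weekly(scenarios: list[GduScenario], path) -> None:
    rows = [
        {"scenario": s.label, "week": j + 1, "gdu": v}
        for s in scenarios
        for j, v in enumerate(s.weekly_gdu)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_temps_daily(path) -> tuple[list[_dt.date], np.ndarray, np.ndarray]:
    """Read a daily min/max temperature table (date, tmax_c, tmin_c)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["date", "tmax_c", "tmin_c"], path)
    try:
        dates = [_dt.date.fromisoformat(str(d)) for d in df["date"]]
    except ValueError as err:
        raise ValueError(f"{path}: bad ISO-8601 date: {err}") from err
    return dates, df["tmax_c"].to_numpy(float), df["tmin_c"].to_numpy(float)


def write_schedule(
    result: SolveResult, instance: Instance, path, allow_unreached: bool = False
) -> None:
    """Write planting weeks and per-scenario harvest weeks.

    Columns: ``id, plant_week, harvest_week_<scenario>...``.  Cells are
    "unreached" only when ``allow_unreached`` is set; otherwise an
    unreached population is an error.
    """
    if result.schedule is None:
        raise ValueError("cannot write an infeasible result")
    rows = []
    for p in instance.populations:
        row = {"id": p.id, "plant_week": result.schedule.plant_week[p.id]}
        for s in instance.scenarios:
            h = result.harvest_week[(p.id, s.label)]
            if h == UNREACHED and not allow_unreached:
                raise ValueError(
                    f"population {p.id} unreached under scenario {s.label!r}; "
                    "pass allow_unreached=True to write anyway"
                )
            row[f"harvest_week_{s.label}"] = h
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("# weeks are 1-based; week 1 is the calendar week containing Jan 1\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_schedule(path) -> PlantingSchedule:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["id", "plant_week"], path)
    return PlantingSchedule(
        plant_week={int(r.id): int(r.plant_week) for r in df.itertuples(index=False)}
    )


def report_weekly(
    result: SolveResult,
    instance: Instance,
    path,
    comparison: Optional[PlantingSchedule] = None,
) -> None:
    """Per-week harvest profile CSV with a summary header block.

    Columns: week, one quantity column per scenario, the cross-scenario
    maximum when K > 1, and the same for an optional comparison schedule
    ("original planting").  The header comments carry the objective, the
    peak week, the active-week count, capacity and the median/max
    absolute deviation from capacity over harvesting weeks.
    """
    if result.profile is None:
        raise ValueError("result has no harvest profile")
    profile = result.profile
    T = instance.T
    data: dict[str, list] = {"week": list(range(1, T + 1))}
    for k, s in enumerate(instance.scenarios):
        data[f"A_{s.label}"] = profile.A[1:, k].tolist()
    if instance.K > 1:
        data["A_max"] = profile.A_max[1:].tolist()
    cmp_profile = None
    if comparison is not None:
        cmp_profile = evaluate_profile(comparison, instance)
        for k, s in enumerate(instance.scenarios):
            data[f"A_{s.label}_comparison"] = cmp_profile.A[1:, k].tolist()
        if instance.K > 1:
            data["A_max_comparison"] = cmp_profile.A_max[1:].tolist()

    am = profile.A_max[1:]
    active = am[am > 0]
    lines = [
        "# weeks are 1-based; week 1 is the calendar week containing Jan 1",
        f"# objective: {result.objective}",
        f"# status: {result.status}",
        f"# active_weeks: {int(active.size)}",
        f"# max_week_quantity: {float(active.max()) if active.size else 0.0}",
    ]
    if instance.capacity is not None:
        dev = np.abs(instance.capacity - active)
        lines += [
            f"# capacity: {instance.capacity}",
            f"# median_abs_deviation: {float(np.median(dev)) if dev.size else 0.0}",
            f"# max_abs_deviation: {float(dev.max()) if dev.size else 0.0}",
        ]
    else:
        lines.append(
            f"# lowest_capacity_required: {float(active.max()) if active.size else 0.0}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        pd.DataFrame(data).to_csv(fh, index=False)
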