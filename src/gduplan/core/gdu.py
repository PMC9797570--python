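"""Growing-degree-unit arithmetic and week-number conventions.

The heat-unit model: daily GDU is the mean of the clamped daily maximum
and minimum air temperatures minus a base temperature (corn: base 10 °C,
cap 30 °C).  Weeks follow the Excel ``WEEKNUM`` default: week 1 runs from
January 1 through the first Saturday; every subsequent week starts on a
Sunday.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import GduScenario, UNREACHED

__all__ = [
    "daily_gdu",
    "week_number",
    "aggregate_weekly",
    "cumulative_gdu",
    "harvest_week",
    "extend_weekly",
]

BASE_TEMP_C = 10.0
CAP_TEMP_C = 30.0


def daily_gdu(
    tmax: float,
    tmin: float,
    base: float = BASE_TEMP_C,
    cap: float = CAP_TEMP_C,
) -> float:
    """Daily growing degree units from min/max air temperature (°C).

    Both temperatures are clamped into ``[base, cap]`` before averaging,
    so the result is always non-negative.

    Parameters
    ----------
    tmax, tmin:
        Daily maximum and minimum air temperature in °C (scalars or
        arrays of equal shape).
    base:
        Temperature below which the crop does not grow (default 10 °C).
    cap:
        Temperature above which extra heat adds no growth (default 30 °C).

    Returns
    -------
    float or ndarray
        ``(clamp(tmax) + clamp(tmin)) / 2 - base``.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if not (np.all(np.isfinite(tmax)) and np.all(np.isfinite(tmin))):
        raise ValueError("temperatures must be finite")
    hi = np.clip(tmax, base, cap)
    lo = np.clip(tmin, base, cap)
    out = (hi + lo) / 2.0 - base
    if out.ndim == 0:
        return float(out)
    return out


def week_number(date: _dt.date, planning_year: Optional[int] = None) -> int:
    """1-based week index of ``date`` under the Sunday-start convention.

    Week 1 begins on January 1 of the planning year and ends on the first
    Saturday; each subsequent week begins on a Sunday (the Excel
    ``WEEKNUM`` default).

    Parameters
    ----------
    date:
        Calendar date.
    planning_year:
        Year whose January 1 anchors week 1.  Defaults to ``date.year``.
        Dates before January 1 of the planning year are rejected.
    """
    if planning_year is None:
        planning_year = date.year
    jan1 = _dt.date(planning_year, 1, 1)
    if date < jan1:
        raise ValueError(f"{date} precedes January 1 of planning year {planning_year}")
    # Sunday-based day-of-week of Jan 1 (Sunday == 0).
    jan1_dow = (jan1.weekday() + 1) % 7
    return ((date - jan1).days + jan1_dow) // 7 + 1


def aggregate_weekly(
    daily_gdu_series: Sequence[float],
    dates: Sequence[_dt.date],
    T: Optional[int] = None,
    label: Optional[str] = None,
) -> GduScenario:
    """Sum a contiguous daily GDU series into weekly bins.

    Bins are defined by :func:`week_number` anchored at the year of the
    first date.  When ``T`` is given the series is truncated to ``T``
    weeks; a series covering fewer than ``T`` weeks is an error (no
    silent padding).

    Raises
    ------
    ValueError
        On length mismatch, gaps in the date series, or a series too
        short for ``T``.
    """
    if len(daily_gdu_series) != len(dates):
        raise ValueError("one daily GDU value per date is required")
    if len(dates) == 0:
        raise ValueError("empty series")
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days != 1:
            raise ValueError(f"gap in date series between {prev} and {cur}")
    year = dates[0].year
    weeks = [week_number(d, planning_year=year) for d in dates]
    n_weeks = weeks[-1]
    totals = np.zeros(n_weeks)
    np.add.at(totals, np.asarray(weeks) - 1, np.asarray(daily_gdu_series, dtype=float))
    if T is not None:
        if n_weeks < T:
            raise ValueError(
                f"series covers {n_weeks} weeks but horizon T={T} requires more; "
                "refusing to pad"
            )
        totals = totals[:T]
    return GduScenario(label if label is not None else str(year), totals)


def cumulative_gdu(scenario: GduScenario) -> np.ndarray:
    """Cumulative heat series ``GDU_0..GDU_T`` with ``GDU_0 = 0``.

    ``cum[j]`` is the total GDU accumulated through the end of week ``j``;
    the sequence is non-decreasing.
    """
    out = np.zeros(scenario.T + 1)
    out[1:] = np.cumsum(scenario.weekly_gdu)
    return out


def harvest_week(
    plant_week: int,
    required_gdu: float,
    cum: np.ndarray,
) -> int | str:
    """Earliest week whose post-planting accumulation reaches the requirement.

    Heat accumulates from the week *after* planting through the harvest
    week inclusive: the harvest week is the smallest ``h`` with
    ``plant_week <= h <= T`` and ``cum[h] - cum[plant_week] >= required_gdu``.
    By minimality ``cum[h-1] - cum[plant_week] < required_gdu``.

    Returns
    -------
    int or str
        The harvest week, or :data:`UNREACHED` when the horizon does not
        supply enough heat.
    """
    cum = np.asarray(cum)
    T = len(cum) - 1
    if not (1 <= plant_week <= T):
        raise ValueError(f"plant_week {plant_week} outside 1..{T}")
    # Same arithmetic as a naive scan over cum[h] - cum[plant_week].
    diffs = cum[plant_week:] - cum[plant_week]
    hits = np.nonzero(diffs >= required_gdu)[0]
    if hits.size == 0:
        return UNREACHED
    return int(plant_week + hits[0])


def extend_weekly(
    values: Sequence[float],
    T: int,
    mode: str = "wrap",
    next_year: Optional[Sequence[float]] = None,
) -> list[float]:
    """Extend a (typically 52-week) series to horizon ``T``.

    ``mode='wrap'`` repeats the same series from week 1 (preserving the
    year's climate identity); ``mode='next_year_series'`` appends the
    supplied ``next_year`` series; ``mode='error'`` refuses.
    """
    values = [float(v) for v in values]
    if len(values) >= T:
        return values[:T]
    missing = T - len(values)
    if mode == "wrap":
        reps = values * (missing // len(values) + 1)
        return values + reps[:missing]
    if mode == "next_year_series":
        if next_year is None or len(next_year) < missing:
            raise ValueError("next_year_series mode needs a long-enough follow-on series")
        return values + [float(v) for v in next_year[:missing]]
    if mode == "error":
        raise ValueError(f"series of length {len(values)} shorter than horizon {T}")
    raise ValueError(f"unknown extension mode {mode!r}")
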