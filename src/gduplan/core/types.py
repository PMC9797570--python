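"""Domain types for the planting/harvest scheduling problem.

Week indexing is 1-based everywhere (weeks ``1..T``).  Cumulative GDU
arrays carry a sentinel ``0`` at index 0 so that ``cum[j]`` is the heat
accumulated through the end of week ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Population",
    "GduScenario",
    "Instance",
    "PlantingSchedule",
    "HarvestProfile",
    "SolveResult",
    "UNREACHED",
    "InfeasibleInstanceError",
]

#: Sentinel returned when a population cannot accumulate its required GDU
#: within the horizon.  A value, not an error.
UNREACHED = "unreached"


class InfeasibleInstanceError(ValueError):
    """Raised when at least one (population, scenario) pair cannot mature.

    Parameters
    ----------
    pairs:
        ``(population_id, scenario_label)`` pairs with no feasible
        planting week.
    """

    def __init__(self, pairs: Sequence[tuple[int, str]]):
        self.pairs = list(pairs)
        self.population_ids = sorted({i for i, _ in self.pairs})
        super().__init__(
            "instance infeasible: no planting week reaches the required GDU for "
            f"{len(self.pairs)} (population, scenario) pair(s); populations "
            f"{self.population_ids}"
        )


@dataclass(frozen=True)
class Population:
    """One seed population: planting window, heat requirement, harvest sizes.

    Attributes
    ----------
    id:
        Integer identifier, unique within an instance.
    earliest_plant_week, latest_plant_week:
        Inclusive 1-based planting window ``[l_i, u_i]``.
    required_gdu:
        Heat units that must accumulate after planting before harvest.
    hq_case1, hq_case2:
        Harvest quantity in ears under the fixed-capacity case and the
        capacity-sizing case respectively.
    """

    id: int
    earliest_plant_week: int
    latest_plant_week: int
    required_gdu: float
    hq_case1: float
    hq_case2: float

    def __post_init__(self) -> None:
        if not (1 <= self.earliest_plant_week <= self.latest_plant_week):
            raise ValueError(
                f"population {self.id}: invalid window "
                f"[{self.earliest_plant_week}, {self.latest_plant_week}]"
            )
        if not self.required_gdu > 0:
            raise ValueError(f"population {self.id}: required_gdu must be > 0")
        if self.hq_case1 < 0 or self.hq_case2 < 0:
            raise ValueError(f"population {self.id}: harvest quantities must be >= 0")

    @property
    def window(self) -> range:
        """Inclusive planting window as a ``range`` of week indices."""
        return range(self.earliest_plant_week, self.latest_plant_week + 1)

    def hq(self, case: int) -> float:
        """Harvest quantity for capacity case ``1`` or ``2``."""
        if case == 1:
            return self.hq_case1
        if case == 2:
            return self.hq_case2
        raise ValueError(f"unknown capacity case {case!r}")


@dataclass(frozen=True)
class GduScenario:
    """One weekly heat-unit series over the planning horizon.

    ``weekly_gdu[j-1]`` is the (non-cumulative) GDU of week ``j``;
    week 1 is the calendar week containing January 1.
    """

    label: str
    weekly_gdu: tuple[float, ...]

    def __init__(self, label: str, weekly_gdu: Iterable[float]):
        object.__setattr__(self, "label", str(label))
        values = tuple(float(v) for v in weekly_gdu)
        if len(values) == 0:
            raise ValueError(f"scenario {label!r}: empty weekly series")
        if any(not np.isfinite(v) or v < 0 for v in values):
            raise ValueError(f"scenario {label!r}: weekly GDU must be finite and >= 0")
        object.__setattr__(self, "weekly_gdu", values)

    @property
    def T(self) -> int:
        return len(self.weekly_gdu)


@dataclass
class Instance:
    """A scheduling instance: populations, GDU scenarios and capacity config.

    ``capacity`` is required for case-1 objectives only.  ``hq_case``
    selects which harvest-quantity column is active.
    """

    populations: list[Population]
    scenarios: list[GduScenario]
    T: int = 70
    capacity: Optional[float] = None
    theta_w: float = 1.0
    hq_case: int = 1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.scenarios) < 1:
            raise ValueError("at least one GDU scenario is required")
        if self.capacity is not None and not self.capacity > 0:
            raise ValueError("capacity must be > 0 when present")
        if self.theta_w < 0:
            raise ValueError("theta_w must be >= 0")
        if self.hq_case not in (1, 2):
            raise ValueError("hq_case must be 1 or 2")
        ids = [p.id for p in self.populations]
        if len(ids) != len(set(ids)):
            raise ValueError("population ids must be unique")
        for p in self.populations:
            if p.latest_plant_week > self.T:
                raise ValueError(
                    f"population {p.id}: window end {p.latest_plant_week} > T={self.T}"
                )
        for s in self.scenarios:
            if s.T != self.T:
                raise ValueError(
                    f"scenario {s.label!r}: length {s.T} != horizon T={self.T}"
                )

    @property
    def N(self) -> int:
        return len(self.populations)

    @property
    def K(self) -> int:
        return len(self.scenarios)

    def hq(self, population: Population) -> float:
        """Active harvest quantity of ``population`` under ``hq_case``."""
        return population.hq(self.hq_case)

    def cumulative(self) -> np.ndarray:
        """Cumulative GDU matrix of shape ``(K, T+1)`` with ``[:, 0] == 0``."""
        out = np.zeros((self.K, self.T + 1))
        for k, s in enumerate(self.scenarios):
            out[k, 1:] = np.cumsum(s.weekly_gdu)
        return out

    def total_hq(self) -> float:
        return float(sum(self.hq(p) for p in self.populations))


@dataclass
class PlantingSchedule:
    """One planting week per population id."""

    plant_week: dict[int, int]

    def validate(self, instance: Instance) -> None:
        """Check window compliance against ``instance``; raise on violation."""
        for p in instance.populations:
            w = self.plant_week.get(p.id)
            if w is None:
                raise ValueError(f"population {p.id}: no planting week assigned")
            if not (p.earliest_plant_week <= w <= p.latest_plant_week):
                raise ValueError(
                    f"population {p.id}: planting week {w} outside window "
                    f"[{p.earliest_plant_week}, {p.latest_plant_week}]"
                )


@dataclass
class HarvestProfile:
    """Weekly harvest quantities induced by a schedule.

    ``A`` has shape ``(T+1, K)``; row 0 is unused padding so that
    ``A[j, k]`` is the quantity harvested in week ``j`` under scenario
    ``k``.  ``A_max[j] = max_k A[j, k]``.  ``harvest_week`` maps
    ``(population id, scenario label)`` to the 1-based harvest week or
    :data:`UNREACHED`.
    """

    A: np.ndarray
    A_max: np.ndarray
    w: np.ndarray
    harvest_week: dict[tuple[int, str], int | str]
    unreached: list[tuple[int, str]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.A.shape[1]

    @property
    def T(self) -> int:
        return self.A.shape[0] - 1

    def active_weeks(self) -> np.ndarray:
        """1-based week indices where ``A_max > 0``."""
        return np.nonzero(self.A_max[1:] > 0)[0] + 1


@dataclass
class SolveResult:
    """Outcome of a solver (MILP or heuristic) run."""

    schedule: Optional[PlantingSchedule]
    objective: Optional[float]
    status: str  # optimal | feasible | infeasible | time_limit
    profile: Optional[HarvestProfile] = None
    harvest_week: Optional[Mapping[tuple[int, str], int | str]] = None
    gap: Optional[float] = None
    extras: dict = field(default_factory=dict)
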