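"""Synthetic scheduling instances with the statistical shape of the challenge data.

The real dataset is not redistributable, so tests and examples run on
generated instances: planting windows a few weeks wide, right-skewed
(log-normal) harvest quantities with the capacity-sizing case larger
than the fixed-capacity case, and seasonal weekly GDU curves with a
site-level offset plus year-to-year noise.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    GduScenario,
    Instance,
    PlantingSchedule,
    Population,
    evaluate_profile,
    feasibility_report,
)

__all__ = ["GeneratorConfig", "generate_populations", "generate_scenarios", "generate_instance"]

logger = logging.getLogger(__name__)

#: Week of the seasonal GDU peak (mid-summer).
_PEAK_WEEK = 27


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic instance generator.

    Ranges are inclusive.  ``climate_mean_peak`` is the mid-summer mean
    weekly GDU; the sinusoidal seasonal curve swings ``climate_amplitude``
    below the peak in winter.  ``site_offset`` shifts the whole curve
    (negative values emulate a cold site).
    """

    n_populations: int = 20
    T: int = 70
    K: int = 10
    seed: int = 0
    window_start_range: tuple[int, int] = (5, 25)
    window_width_range: tuple[int, int] = (1, 4)
    required_gdu_range: tuple[float, float] = (800.0, 1600.0)
    hq_log_mean: float = 5.0
    hq_log_sd: float = 0.5
    case2_multiplier_range: tuple[float, float] = (1.2, 2.5)
    climate_mean_peak: float = 120.0
    climate_amplitude: float = 55.0
    climate_noise_sd: float = 8.0
    site_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_populations < 0:
            raise ValueError("n_populations must be >= 0")
        if self.T < 1 or self.K < 1:
            raise ValueError("T and K must be >= 1")
        for name in (
            "window_start_range",
            "window_width_range",
            "required_gdu_range",
            "case2_multiplier_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if self.window_start_range[0] < 1 or self.window_start_range[1] > self.T:
            raise ValueError("window_start_range outside 1..T")
        if self.window_width_range[0] < 1:
            raise ValueError("window widths must be >= 1")
        if self.required_gdu_range[0] <= 0:
            raise ValueError("required GDU must be > 0")
        if self.case2_multiplier_range[0] < 1.0:
            raise ValueError("case-2 multiplier must be >= 1")
        if self.climate_noise_sd < 0:
            raise ValueError("climate_noise_sd must be >= 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def generate_populations(cfg: GeneratorConfig) -> list[Population]:
    """Draw the population table: windows, heat requirements, harvest sizes.

    Harvest quantities are integer ear counts drawn log-normally (right
    skew); the case-2 quantity is the case-1 quantity times a multiplier
    > 1, so case 2 always dominates case 1.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    pops = []
    for i in range(cfg.n_populations):
        start = int(rng.integers(cfg.window_start_range[0], cfg.window_start_range[1] + 1))
        width = int(rng.integers(cfg.window_width_range[0], cfg.window_width_range[1] + 1))
        end = min(start + width - 1, cfg.T)
        gmin = float(rng.uniform(*cfg.required_gdu_range))
        hq1 = max(1, int(round(rng.lognormal(cfg.hq_log_mean, cfg.hq_log_sd))))
        mult = float(rng.uniform(*cfg.case2_multiplier_range))
        hq2 = max(hq1, int(round(hq1 * mult)))
        pops.append(
            Population(
                id=i,
                earliest_plant_week=start,
                latest_plant_week=end,
                required_gdu=gmin,
                hq_case1=float(hq1),
                hq_case2=float(hq2),
            )
        )
    return pops


def seasonal_mean(week: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Noise-free mean weekly GDU for (1-based) calendar ``week`` indices."""
    mid = cfg.climate_mean_peak - cfg.climate_amplitude
    return (
        mid
        + cfg.climate_amplitude * np.cos(2 * np.pi * (week - _PEAK_WEEK) / 52.0)
        + cfg.site_offset
    )


def generate_scenarios(cfg: GeneratorConfig) -> list[GduScenario]:
    """Draw ``K`` weekly GDU series of length ``T``.

    Each series is the seasonal sinusoid (52-week period, so the horizon
    beyond week 52 wraps into the next spring) plus independent Gaussian
    noise, clipped at zero.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    weeks = np.arange(1, cfg.T + 1)
    base = seasonal_mean(weeks, cfg)
    scenarios = []
    for k in range(cfg.K):
        noise = rng.normal(0.0, cfg.climate_noise_sd, size=cfg.T) if cfg.climate_noise_sd else 0.0
        series = np.clip(base + noise, 0.0, None)
        scenarios.append(GduScenario(label=f"yr{2010 + k}", weekly_gdu=series))
    return scenarios


def generate_instance(
    cfg: GeneratorConfig,
    capacity_rule: str = "quantile",
    capacity: Optional[float] = None,
    capacity_quantile: float = 0.75,
    hq_case: int = 1,
    theta_w: float = 1.0,
    allow_infeasible: bool = False,
) -> Instance:
    """Assemble a full instance from a generator config.

    Capacity is either explicit (``capacity_rule='explicit'``) or a
    quantile of the active weekly envelope under midpoint-of-window
    planting.  By default any population whose requirement is unreachable
    from every window week under some scenario has its requirement
    resampled downward (logged); ``allow_infeasible=True`` keeps such
    populations to exercise infeasibility reporting.
    """
    pops = generate_populations(cfg)
    scenarios = generate_scenarios(cfg)
    rng = np.random.default_rng([cfg.seed, 3])

    cum = np.zeros((cfg.K, cfg.T + 1))
    for k, s in enumerate(scenarios):
        cum[k, 1:] = np.cumsum(s.weekly_gdu)

    if not allow_infeasible:
        repaired = []
        for p in pops:
            # max accumulation available when planted at the earliest window week
            reach = min(cum[k, cfg.T] - cum[k, p.earliest_plant_week] for k in range(cfg.K))
            if p.required_gdu > reach:
                if reach <= 0:
                    raise ValueError(
                        f"population {p.id}: no heat available after week "
                        f"{p.earliest_plant_week}; widen the climate config"
                    )
                new_g = float(rng.uniform(0.5 * reach, 0.95 * reach))
                logger.info(
                    "resampled required_gdu of population %d: %.1f -> %.1f",
                    p.id, p.required_gdu, new_g,
                )
                p = Population(
                    id=p.id,
                    earliest_plant_week=p.earliest_plant_week,
                    latest_plant_week=p.latest_plant_week,
                    required_gdu=new_g,
                    hq_case1=p.hq_case1,
                    hq_case2=p.hq_case2,
                )
            repaired.append(p)
        pops = repaired

    if capacity_rule == "explicit":
        if capacity is None:
            raise ValueError("capacity_rule='explicit' requires a capacity value")
        cap = float(capacity)
    elif capacity_rule == "quantile":
        cap = _quantile_capacity(pops, scenarios, cfg.T, hq_case, capacity_quantile)
    elif capacity_rule == "none":
        cap = None
    else:
        raise ValueError(f"unknown capacity_rule {capacity_rule!r}")

    instance = Instance(
        populations=pops,
        scenarios=scenarios,
        T=cfg.T,
        capacity=cap,
        theta_w=theta_w,
        hq_case=hq_case,
    )
    if not allow_infeasible:
        report = feasibility_report(instance)
        assert report.feasible, "feasibility repair failed"
    return instance


def _quantile_capacity(pops, scenarios, T, hq_case, q) -> float:
    """Capacity as a quantile of active weekly demand under midpoint planting."""
    if not pops:
        return 1.0
    midpoint = {
        p.id: (p.earliest_plant_week + p.latest_plant_week) // 2 for p in pops
    }
    inst = Instance(
        populations=pops, scenarios=scenarios, T=T, capacity=None, hq_case=hq_case
    )
    profile = evaluate_profile(PlantingSchedule(plant_week=midpoint), inst)
    active = profile.A_max[1:][profile.A_max[1:] > 0]
    if active.size == 0:
        return 1.0
    return float(math.ceil(np.quantile(active, q)))
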