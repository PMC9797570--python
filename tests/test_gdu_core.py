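"""Unit and property tests for the GDU engine, objectives and diagnostics."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gduplan.core import (
    GduScenario,
    Instance,
    PlantingSchedule,
    Population,
    UNREACHED,
    aggregate_weekly,
    count_stochastic_milp_variables,
    cumulative_gdu,
    daily_gdu,
    evaluate_profile,
    extend_weekly,
    feasibility_report,
    harvest_week,
    objective_case1_det,
    objective_case1_stoch,
    objective_case2_det,
    objective_case2_stoch,
    week_number,
)
from gduplan.core.types import HarvestProfile


# ---------------------------------------------------------------- daily_gdu
class TestDailyGdu:
    def test_direct_substitution(self):
        assert daily_gdu(30, 10) == 10.0

    def test_both_clamp_to_cap(self):
        assert daily_gdu(35, 30) == 20.0

    def test_below_base_is_zero(self):
        assert daily_gdu(8, 2) == 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            daily_gdu(float("nan"), 10)
        with pytest.raises(ValueError):
            daily_gdu(20, float("inf"))

    def test_vectorized(self):
        out = daily_gdu(np.array([30.0, 35.0, 8.0]), np.array([10.0, 30.0, 2.0]))
        np.testing.assert_allclose(out, [10.0, 20.0, 0.0])

    @given(
        tmax=st.floats(-40, 60, allow_nan=False),
        tmin=st.floats(-40, 60, allow_nan=False),
    )
    def test_always_in_range(self, tmax, tmin):
        assert 0.0 <= daily_gdu(tmax, tmin) <= 20.0


# -------------------------------------------------------------- week_number
def _weeknum_oracle(date: dt.date) -> int:
    """Independent enumeration: walk days from Jan 1, bumping on Sundays."""
    week, day = 1, dt.date(date.year, 1, 1)
    while day < date:
        day += dt.timedelta(days=1)
        if day.weekday() == 6:  # Sunday
            week += 1
    return week


class TestWeekNumber:
    def test_jan_first_is_week_one(self):
        for year in (2019, 2020, 2021, 2022):
            assert week_number(dt.date(year, 1, 1)) == 1

    def test_first_sunday_starts_week_two(self):
        d = dt.date(2021, 1, 2)  # Jan 1 2021 was a Friday
        while d.weekday() != 6:
            d += dt.timedelta(days=1)
        assert week_number(d) == 2

    def test_dec31_2020_is_week_53(self):
        assert week_number(dt.date(2020, 12, 31)) == 53

    def test_matches_enumeration_oracle_across_2020(self):
        d = dt.date(2020, 1, 1)
        while d.year == 2020:
            assert week_number(d) == _weeknum_oracle(d)
            d += dt.timedelta(days=1)

    def test_rejects_dates_before_planning_year(self):
        with pytest.raises(ValueError):
            week_number(dt.date(2019, 12, 31), planning_year=2020)


# --------------------------------------------------------- aggregate_weekly
class TestAggregateWeekly:
    def test_constant_week_sums_to_seventy(self):
        dates = [dt.date(2021, 1, 3) + dt.timedelta(days=i) for i in range(7)]
        scen = aggregate_weekly([10.0] * 7, dates)
        assert scen.weekly_gdu[-1] == 70.0

    def test_partial_first_week(self):
        # 2020 started on a Wednesday: week 1 holds only Wed-Sat.
        dates = [dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(14)]
        scen = aggregate_weekly([1.0] * 14, dates)
        assert scen.weekly_gdu[0] == 4.0
        assert scen.weekly_gdu[1] == 7.0

    def test_full_2020_gives_53_bins(self):
        dates = [dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(366)]
        scen = aggregate_weekly([1.0] * 366, dates)
        assert scen.T == 53
        assert sum(scen.weekly_gdu) == 366.0

    def test_gap_rejected(self):
        dates = [dt.date(2021, 1, 1), dt.date(2021, 1, 3)]
        with pytest.raises(ValueError, match="gap"):
            aggregate_weekly([1.0, 1.0], dates)

    def test_padding_is_an_error(self):
        dates = [dt.date(2021, 1, 1) + dt.timedelta(days=i) for i in range(14)]
        with pytest.raises(ValueError, match="pad"):
            aggregate_weekly([1.0] * 14, dates, T=70)


# ----------------------------------------------------------- cumulative_gdu
class TestCumulativeGdu:
    def test_running_sum(self):
        cum = cumulative_gdu(GduScenario("s", [5, 10, 20]))
        np.testing.assert_allclose(cum, [0, 5, 15, 35])

    def test_all_zero(self):
        cum = cumulative_gdu(GduScenario("s", [0, 0, 0]))
        np.testing.assert_allclose(cum, np.zeros(4))

    def test_conservation(self, rng):
        weekly = rng.uniform(0, 100, size=30)
        cum = cumulative_gdu(GduScenario("s", weekly))
        assert cum[0] == 0.0
        assert cum[-1] == pytest.approx(weekly.sum())
        assert np.all(np.diff(cum) >= 0)


# ------------------------------------------------------------- harvest_week
class TestHarvestWeek:
    def test_linear_scan_example(self):
        assert harvest_week(1, 300, np.array([0, 100, 250, 400, 600])) == 3

    def test_first_positive_week_after_planting(self):
        assert harvest_week(2, 0.5, np.array([0, 10, 20, 30])) == 3

    def test_unreached(self):
        cum = np.concatenate([[0], np.cumsum(np.full(70, 100.0))])
        assert harvest_week(1, 1e6, cum) == UNREACHED

    def test_invalid_plant_week(self):
        with pytest.raises(ValueError):
            harvest_week(0, 10, np.array([0, 10, 20]))

    @settings(max_examples=200, deadline=None)
    @given(
        weekly=st.lists(st.floats(0, 200), min_size=3, max_size=30),
        plant_frac=st.floats(0, 1),
        gmin=st.floats(0.1, 4000),
    )
    def test_minimality_pair_property(self, weekly, plant_frac, gmin):
        cum = np.concatenate([[0.0], np.cumsum(weekly)])
        T = len(weekly)
        plant = 1 + int(plant_frac * (T - 1))
        h = harvest_week(plant, gmin, cum)
        # naive scan oracle
        naive = UNREACHED
        for j in range(plant, T + 1):
            if cum[j] - cum[plant] >= gmin:
                naive = j
                break
        assert h == naive
        if h != UNREACHED:
            assert cum[h] - cum[plant] >= gmin
            assert cum[h - 1] - cum[plant] < gmin

    def test_monotonicity_in_scenario(self, rng):
        # pointwise-increasing the weekly series never delays harvest
        for _ in range(50):
            weekly = rng.uniform(0, 60, size=20)
            boost = weekly + rng.uniform(0, 30, size=20)
            plant = int(rng.integers(1, 10))
            gmin = float(rng.uniform(10, 600))
            h1 = harvest_week(plant, gmin, np.concatenate([[0], np.cumsum(weekly)]))
            h2 = harvest_week(plant, gmin, np.concatenate([[0], np.cumsum(boost)]))
            if h1 != UNREACHED:
                assert h2 != UNREACHED and h2 <= h1


# ------------------------------------------------------------ extend_weekly
class TestExtendWeekly:
    def test_wrap(self):
        assert extend_weekly([1, 2, 3], 7, mode="wrap") == [1, 2, 3, 1, 2, 3, 1]

    def test_truncate(self):
        assert extend_weekly([1, 2, 3, 4], 2, mode="wrap") == [1, 2]

    def test_error_mode(self):
        with pytest.raises(ValueError):
            extend_weekly([1, 2], 5, mode="error")

    def test_next_year_series(self):
        assert extend_weekly([1, 2], 4, mode="next_year_series", next_year=[9, 8, 7]) == [1, 2, 9, 8]


# --------------------------------------------------------- evaluate_profile
class TestEvaluateProfile:
    def test_single_population_single_cell(self, single_pop_instance):
        sched = PlantingSchedule({1: 1})
        profile = evaluate_profile(sched, single_pop_instance)
        nonzero = np.nonzero(profile.A)
        assert len(nonzero[0]) == 1
        assert profile.A[nonzero][0] == 100.0
        # plant week 1: cum through week 3 (80+120+150=350) >= 300, week 2 short
        assert profile.harvest_week[(1, "s")] == 4  # 80+120+150 >= 300 at week 4? checked below

    def test_identical_scenarios_share_envelope(self, simple_scenario):
        twin = GduScenario("s2", simple_scenario.weekly_gdu)
        pop = Population(1, 1, 2, 300.0, 100.0, 150.0)
        inst = Instance([pop], [simple_scenario, twin], T=10, capacity=100.0)
        profile = evaluate_profile(PlantingSchedule({1: 2}), inst)
        np.testing.assert_array_equal(profile.A[:, 0], profile.A[:, 1])
        np.testing.assert_array_equal(profile.A_max, profile.A[:, 0])

    def test_conservation_per_scenario(self):
        from _helpers import toy_stochastic_instance

        inst = toy_stochastic_instance(seed=7, n=5, k=3, T=18)
        sched = PlantingSchedule({p.id: p.earliest_plant_week for p in inst.populations})
        profile = evaluate_profile(sched, inst)
        assert not profile.unreached
        total = sum(inst.hq(p) for p in inst.populations)
        for k in range(inst.K):
            assert profile.A[:, k].sum() == pytest.approx(total)

    def test_window_violation_rejected(self, single_pop_instance):
        with pytest.raises(ValueError, match="outside window"):
            evaluate_profile(PlantingSchedule({1: 5}), single_pop_instance)

    def test_unreached_listed_not_dropped(self, simple_scenario):
        pop = Population(1, 1, 1, 100_000.0, 50.0, 60.0)
        inst = Instance([pop], [simple_scenario], T=10, capacity=10.0)
        profile = evaluate_profile(PlantingSchedule({1: 1}), inst)
        assert profile.unreached == [(1, "s")]
        assert profile.A.sum() == 0.0


def _profile_from_columns(columns: np.ndarray) -> HarvestProfile:
    """Build a bare profile from a (T, K) weekly-quantity array."""
    T, K = columns.shape
    A = np.zeros((T + 1, K))
    A[1:] = columns
    return HarvestProfile(
        A=A, A_max=A.max(axis=1), w=A > 0, harvest_week={}, unreached=[]
    )


# --------------------------------------------------------------- objectives
class TestObjectives:
    def test_case1_det_examples(self):
        p = _profile_from_columns(np.array([[10.0], [8.0], [0.0]]))
        assert objective_case1_det(p, 10) == 2.0
        assert objective_case1_det(_profile_from_columns(np.zeros((3, 1))), 10) == 0.0
        p = _profile_from_columns(np.array([[6900.0], [7100.0]]))
        assert objective_case1_det(p, 7000) == 200.0

    def test_case1_det_rejects_multi_scenario(self):
        with pytest.raises(ValueError):
            objective_case1_det(_profile_from_columns(np.zeros((3, 2))), 10)

    def test_case1_stoch_examples(self):
        p = _profile_from_columns(np.array([[6000.0], [5900.0], [0.0], [0.0]]))
        assert objective_case1_stoch(p, 6000) == 100.0
        assert objective_case1_stoch(p, 6000, all_weeks=True) == 12_100.0
        full = _profile_from_columns(np.array([[7000.0], [7000.0]]))
        assert objective_case1_stoch(full, 7000) == 0.0

    def test_case2_det_examples(self):
        p = _profile_from_columns(np.array([[5.0], [9.0], [0.0]]))
        assert objective_case2_det(p, theta_w=1.0) == 11.0
        assert objective_case2_det(_profile_from_columns(np.array([[4.0]])), 0.0) == 4.0
        assert objective_case2_det(_profile_from_columns(np.zeros((4, 1)))) == 0.0

    def test_case2_stoch_examples(self):
        p = _profile_from_columns(np.array([[100.0], [100.0], [100.0]]))
        assert objective_case2_stoch(p) == 0.0
        p = _profile_from_columns(np.array([[50.0], [80.0], [60.0]]))
        assert objective_case2_stoch(p) == 50.0
        assert objective_case2_stoch(_profile_from_columns(np.array([[42.0]]))) == 0.0

    def test_case2_stoch_nonnegative_zero_iff_constant(self, rng):
        for _ in range(30):
            cols = rng.integers(0, 5, size=(8, 2)).astype(float) * 37
            p = _profile_from_columns(cols)
            v = objective_case2_stoch(p)
            assert v >= 0
            active = p.A_max[1:][p.A_max[1:] > 0]
            assert (v == 0) == (active.size <= 1 or np.all(active == active[0]))


# --------------------------------------------------------------- feasibility
class TestFeasibility:
    def test_generous_scenario_all_feasible(self):
        from _helpers import toy_stochastic_instance

        inst = toy_stochastic_instance(seed=1)
        assert feasibility_report(inst).feasible

    def test_scaled_down_scenario_infeasible(self, simple_scenario):
        pops = [Population(i, 1, 2, 300.0, 10.0, 20.0) for i in range(3)]
        tiny = GduScenario("cold", [v * 0.1 for v in simple_scenario.weekly_gdu])
        inst = Instance(pops, [simple_scenario, tiny], T=10, capacity=10.0)
        report = feasibility_report(inst)
        assert not report.feasible
        assert {(i, "cold") for i in range(3)} == set(report.offending_pairs)

    def test_one_bad_scenario_suffices(self, simple_scenario):
        # feasible under the warm scenario, not under the cold one
        pop = Population(1, 1, 1, 500.0, 10.0, 20.0)
        cold = GduScenario("cold", [v * 0.2 for v in simple_scenario.weekly_gdu])
        inst = Instance([pop], [simple_scenario, cold], T=10, capacity=10.0)
        report = feasibility_report(inst)
        assert not report.feasible
        assert report.offending_pairs == [(1, "cold")]
        assert report.reachable[(1, "s")]


# ----------------------------------------------------------- variable count
class TestVariableCount:
    @pytest.mark.parametrize(
        "n,k,t,expected",
        [(100, 10, 70, 77_770), (1194, 10, 70, 920_150), (1, 1, 1, 4)],
    )
    def test_printed_counts(self, n, k, t, expected):
        assert count_stochastic_milp_variables(n, k, t) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            count_stochastic_milp_variables(0, 10, 70)
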