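"""Cost and QALY accrual with continuous-time discounting."""

import math

import pytest
from hypothesis import given, strategies as st

from polypillsim.economics import (CostTable, UtilityTable, accrue_costs,
                                   accrue_qalys, discounted_outcome,
                                   flow_present_value, polypill_annual_cost,
                                   present_value)
from polypillsim.engine import (EventRecord, EventType, ExposureInterval,
                                Trajectory)
from polypillsim.errors import ContractError


def bare_trajectory(exit_time=10.0, arm="usual", sex="male", entry_age=60.0,
                    events=(), exposure=()):
    return Trajectory(individual_id=0, arm=arm, entry_age=entry_age, sex=sex,
                      events=list(events), exposure=list(exposure),
                      exit_reason="death", exit_time=exit_time)


def unit_utilities():
    return UtilityTable(baseline={"male": ((18.0, 1.0),),
                                  "female": ((18.0, 1.0),)},
                        decrements={}, transient={})


class TestPolypillPrice:
    def test_aggregate_of_components(self):
        assert polypill_annual_cost([10, 20, 5, 5]) == 40.0

    def test_single_component(self):
        assert polypill_annual_cost([17.5]) == 17.5

    def test_sensitivity_override_wins(self):
        assert polypill_annual_cost([10, 20, 5, 5], override=12.0) == 12.0

    def test_cost_table_default_equals_component_sum(self):
        costs = CostTable()
        assert costs.polypill_cost() == pytest.approx(
            sum(costs.annual_med.values()))


class TestDiscounting:
    def test_point_cost_one_year(self):
        assert present_value(1000.0, 1.0, 0.035) == \
            pytest.approx(1000 / 1.035, abs=5e-3)
        assert round(present_value(1000.0, 1.0, 0.035), 2) == 966.18

    def test_flow_closed_form(self):
        got = flow_present_value(100.0, 0.0, 10.0, 0.035)
        expected = 100 * (1 - 1.035 ** -10) / math.log(1.035)
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(got, 2) == 846.13

    def test_zero_rate_is_plain_sum(self):
        assert flow_present_value(100.0, 2.0, 7.0, 0.0) == 500.0
        assert present_value(123.0, 4.0, 0.0) == 123.0

    @given(split=st.floats(0.1, 9.9))
    def test_flow_additive_over_partition(self, split):
        whole = flow_present_value(80.0, 0.0, 10.0, 0.035)
        parts = flow_present_value(80.0, 0.0, split, 0.035) + \
            flow_present_value(80.0, split, 10.0, 0.035)
        assert parts == pytest.approx(whole, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ContractError):
            present_value(1.0, -0.5, 0.035)


class TestCostAccrual:
    def test_acute_cost_discounted_at_event_time(self):
        costs = CostTable()
        traj = bare_trajectory(events=[
            EventRecord(1.0, EventType.STROKE, False, 61.0)])
        # acute stroke at t=1 plus the stroke state flow from 1 to 10
        expected = (present_value(costs.acute["stroke"], 1.0, 0.035)
                    + flow_present_value(costs.annual_state["stroke"], 1.0,
                                         10.0, 0.035))
        assert accrue_costs(traj, costs, 0.035) == pytest.approx(expected)

    def test_stopping_cost_once_at_cessation(self):
        costs = CostTable()
        traj = bare_trajectory(events=[
            EventRecord(2.0, EventType.CESSATION, False, 62.0)])
        assert accrue_costs(traj, costs, 0.0) == costs.stopping_cost

    def test_medication_only_while_adherent_monitoring_while_treated(self):
        costs = CostTable()
        traj = bare_trajectory(exposure=[
            ExposureInterval(0.0, 4.0, True, True),
            ExposureInterval(4.0, 10.0, True, False)])
        expected = (costs.monitoring_annual * 10.0
                    + costs.usual_med_annual() * 4.0)
        assert accrue_costs(traj, costs, 0.0) == pytest.approx(expected)

    def test_polypill_arm_priced_by_polypill(self):
        costs = CostTable(polypill_annual=200.0)
        traj = bare_trajectory(arm="polypill", exposure=[
            ExposureInterval(0.0, 10.0, True, True)])
        assert accrue_costs(traj, costs, 0.0) == pytest.approx(
            (200.0 + costs.monitoring_annual) * 10.0)

    def test_repeat_events_retrigger_acute_only(self):
        costs = CostTable()
        one = bare_trajectory(events=[
            EventRecord(1.0, EventType.MI, False, 61.0)])
        two = bare_trajectory(events=[
            EventRecord(1.0, EventType.MI, False, 61.0),
            EventRecord(5.0, EventType.MI, False, 65.0)])
        assert accrue_costs(two, costs, 0.0) - accrue_costs(one, costs, 0.0) \
            == pytest.approx(costs.acute["mi"])


class TestQalyAccrual:
    def test_unit_utility_one_year_no_discount(self):
        traj = bare_trajectory(exit_time=1.0)
        assert accrue_qalys(traj, unit_utilities(), 0.0) == pytest.approx(1.0)

    def test_unit_utility_ten_years_discounted(self):
        traj = bare_trajectory(exit_time=10.0)
        assert accrue_qalys(traj, unit_utilities(), 0.035) == \
            pytest.approx((1 - 1.035 ** -10) / math.log(1.035), abs=5e-5)

    def test_decrements_floor_at_zero(self):
        utils = UtilityTable(
            baseline={"male": ((18.0, 0.8),), "female": ((18.0, 0.8),)},
            decrements={"stroke": 0.5, "heart_failure": 0.4},
            transient={})
        traj = bare_trajectory(exit_time=2.0, events=[
            EventRecord(1.0, EventType.STROKE, False, 61.0),
            EventRecord(1.0, EventType.HEART_FAILURE, False, 61.0)])
        # year 1 at 0.8, year 2 floored at 0 (0.8 - 0.9 < 0)
        assert accrue_qalys(traj, utils, 0.0) == pytest.approx(0.8)

    def test_transient_decrement_expires(self):
        utils = UtilityTable(
            baseline={"male": ((18.0, 1.0),), "female": ((18.0, 1.0),)},
            decrements={}, transient={"gi_bleed": (0.2, 0.5)})
        traj = bare_trajectory(exit_time=2.0, events=[
            EventRecord(1.0, EventType.GI_BLEED, False, 61.0)])
        assert accrue_qalys(traj, utils, 0.0) == pytest.approx(2.0 - 0.2 * 0.5)

    def test_age_band_crossing_lowers_utility(self):
        utils = UtilityTable(
            baseline={"male": ((18.0, 0.9), (65.0, 0.7)),
                      "female": ((18.0, 0.9), (65.0, 0.7))},
            decrements={}, transient={})
        traj = bare_trajectory(exit_time=10.0, entry_age=60.0)
        assert accrue_qalys(traj, utils, 0.0) == \
            pytest.approx(0.9 * 5 + 0.7 * 5)

    def test_qalys_bounded_by_life_years(self, default_params, small_cohort):
        from polypillsim.analysis import individual_rng
        from polypillsim.config import ScenarioConfig
        from polypillsim.engine import simulate_individual
        scen = ScenarioConfig(arm="usual", master_seed=2)
        for i, ind in enumerate(small_cohort[:50]):
            traj = simulate_individual(ind, scen, default_params,
                                       individual_rng(2, i))
            out = discounted_outcome(traj, default_params.costs,
                                     default_params.utilities,
                                     default_params.discount_rate)
            assert out.qalys_undiscounted <= traj.exit_time + 1e-9
            assert out.qalys <= out.qalys_undiscounted + 1e-9
            assert out.cost <= out.cost_undiscounted + 1e-9


def test_zero_rate_equals_undiscounted_on_simulated_profiles(
        default_params, small_cohort):
    from polypillsim.analysis import individual_rng
    from polypillsim.config import ScenarioConfig
    from polypillsim.engine import simulate_individual
    scen = ScenarioConfig(arm="polypill", master_seed=9)
    for i, ind in enumerate(small_cohort[:20]):
        traj = simulate_individual(ind, scen, default_params,
                                   individual_rng(9, i))
        assert accrue_costs(traj, default_params.costs, 0.0) == pytest.approx(
            discounted_outcome(traj, default_params.costs,
                               default_params.utilities, 0.035
                               ).cost_undiscounted)
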