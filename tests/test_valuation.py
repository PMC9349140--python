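"""Costing, discounting, QALY and incremental-comparison rules."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as hs

from mscua import (CostItem, UtilityParams, ValidationError, WageParams,
                   accrue_costs, compare_strategies, compute_lys_qalys,
                   discount_total, net_monetary_benefit, run_cohort_trace,
                   value_time_loss)
from mscua.valuation import (DOMINATED, HEALTHCARE_SECTOR, ICUR_REPORTED,
                             OUT_OF_POCKET, STRONGLY_DOMINANT, EconOutcome)

from conftest import make_strategy


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        assert discount_total([10, 10, 10], rate=0.0) == pytest.approx(30.0)

    def test_single_term_closed_form(self):
        assert discount_total([103.0], rate=0.03, times=[1]) == pytest.approx(
            100.0)

    def test_seven_unit_values_match_direct_summation(self):
        # independent oracle: direct summation of 1.03^-t for t = 1..7
        oracle = sum(1.03 ** -t for t in range(1, 8))
        got = discount_total(np.ones(7), rate=0.03, times=range(1, 8))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert round(got, 4) == 6.2303

    def test_default_times_leave_first_cycle_undiscounted(self):
        assert discount_total([100.0], rate=0.03) == pytest.approx(100.0)

    @given(rate1=hs.floats(0.0, 0.2), bump=hs.floats(0.01, 0.2))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_rate(self, rate1, bump):
        stream = np.array([5.0, 7.0, 3.0, 9.0])
        assert discount_total(stream, rate1, times=[1, 2, 3, 4]) > \
            discount_total(stream, rate1 + bump, times=[1, 2, 3, 4])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_total([1.0], rate=-0.01)


class TestTimeValuation:
    wages = WageParams(gross_hourly_wage=20.0, take_home_hourly_wage=12.0,
                       homehelper_gross_wage=10.0)

    @pytest.mark.parametrize("hours,age,role,expected", [
        (10, 35, "patient", 200.0),            # working time at gross wage
        (10, 72, "patient", 120.0),            # leisure time at take-home
        (10, 35, "caregiver", 120.0),          # caregivers always take-home
        (10, 35, "housekeeper-patient", 100.0),
        (0, 35, "patient", 0.0),
    ])
    def test_wage_rules(self, hours, age, role, expected):
        assert value_time_loss(hours, age, role, self.wages) == pytest.approx(
            expected)

    def test_negative_hours_rejected(self):
        with pytest.raises(ValidationError):
            value_time_loss(-1.0, 35, "patient", self.wages)

    def test_gross_below_take_home_rejected(self):
        with pytest.raises(ValidationError):
            WageParams(gross_hourly_wage=10.0, take_home_hourly_wage=12.0,
                       homehelper_gross_wage=10.0)


class TestCostAccrual:
    def _trace(self):
        return run_cohort_trace(make_strategy(q=0.0, p_relapse=0.0),
                                n0=1000, n_cycles=7)

    def test_admin_tariff_is_halved(self):
        trace = self._trace()
        item = CostItem(name="admin", category=HEALTHCARE_SECTOR,
                        attach_to="state:CONTROLLED", unit_cost=200.0,
                        is_admin_tariff=True)
        by_cat, _ = accrue_costs(trace, [item], rate=0.0)
        assert by_cat[HEALTHCARE_SECTOR] == pytest.approx(100.0 * 7)

    def test_empty_item_list_costs_nothing(self):
        by_cat, by_item = accrue_costs(self._trace(), [], rate=0.0)
        assert all(v == 0.0 for v in by_cat.values())
        assert by_item == {}

    def test_unit_item_on_full_occupancy_costs_seven(self):
        item = CostItem(name="x", category=HEALTHCARE_SECTOR,
                        attach_to="state:CONTROLLED", unit_cost=1.0)
        by_cat, _ = accrue_costs(self._trace(), [item], rate=0.0)
        assert by_cat[HEALTHCARE_SECTOR] == pytest.approx(7.0)

    def test_entry_item_charged_once_undiscounted(self):
        item = CostItem(name="assess", category=HEALTHCARE_SECTOR,
                        attach_to="event:entry", unit_cost=113.34)
        by_cat, _ = accrue_costs(self._trace(), [item], rate=0.10)
        assert by_cat[HEALTHCARE_SECTOR] == pytest.approx(113.34)

    def test_unknown_attachment_rejected(self):
        with pytest.raises(ValidationError, match="unknown attachment"):
            CostItem(name="bad", category=HEALTHCARE_SECTOR,
                     attach_to="state:NOWHERE", unit_cost=1.0)

    def test_adherence_scales_flagged_items_only(self):
        trace = self._trace()
        drug = CostItem(name="drug", category=HEALTHCARE_SECTOR,
                        attach_to="state:CONTROLLED", unit_cost=100.0,
                        scales_with_adherence=True)
        visit = CostItem(name="visit", category=HEALTHCARE_SECTOR,
                         attach_to="state:CONTROLLED", unit_cost=100.0)
        by_cat, by_item = accrue_costs(trace, [drug, visit], rate=0.0,
                                       adherence=0.5)
        assert by_item["drug"] == pytest.approx(0.5 * by_item["visit"])


class TestLysQalys:
    def test_perfect_survival_full_utility(self):
        trace = run_cohort_trace(make_strategy(), n0=1000, n_cycles=7)
        up = UtilityParams(1.0, 1.0, 1.0)
        lys, qalys = compute_lys_qalys(trace, up, rate=0.0)
        assert lys == pytest.approx(7.0)
        assert qalys == pytest.approx(7.0)

    def test_half_utility_halves_qalys(self):
        trace = run_cohort_trace(make_strategy(q=0.05, p_relapse=0.3),
                                 n0=1000, n_cycles=7)
        up = UtilityParams(0.5, 0.5, 0.5)
        lys, qalys = compute_lys_qalys(trace, up, rate=0.03)
        assert qalys == pytest.approx(lys / 2)

    def test_qalys_bounded_by_lys_and_horizon(self):
        trace = run_cohort_trace(make_strategy(q=0.02, p_relapse=0.4,
                                               p_remission=0.3),
                                 n0=1000, n_cycles=7)
        up = UtilityParams(0.9, 0.4, 0.7, ae_disutility=0.02)
        lys, qalys = compute_lys_qalys(trace, up, rate=0.03)
        assert 0.0 <= qalys <= lys <= 7.0


def _outcome(cost, qalys, perspective=HEALTHCARE_SECTOR, strategy="s"):
    return EconOutcome(strategy=strategy, perspective=perspective,
                       cost_by_category={HEALTHCARE_SECTOR: cost,
                                         OUT_OF_POCKET: 0.0,
                                         "TIME_AND_INFORMAL_CARE": 0.0},
                       lys=7.0, qalys=qalys)


class TestComparison:
    def test_cheaper_and_better_is_strongly_dominant(self):
        r = compare_strategies(_outcome(98957.32, 3.603),
                               _outcome(100000.0, 3.123))
        assert r.verdict == STRONGLY_DOMINANT
        assert r.delta_cost == pytest.approx(-1042.68)
        assert r.delta_qalys == pytest.approx(0.480)

    def test_equal_outcomes_leave_icur_undefined(self):
        r = compare_strategies(_outcome(100.0, 1.0), _outcome(100.0, 1.0))
        assert r.verdict == ICUR_REPORTED
        assert not r.icur_defined

    def test_plain_ratio(self):
        r = compare_strategies(_outcome(1100.0, 1.5), _outcome(100.0, 1.0))
        assert r.icur == pytest.approx(2000.0)
        assert r.verdict == ICUR_REPORTED

    def test_dominated_quadrant(self):
        r = compare_strategies(_outcome(200.0, 0.5), _outcome(100.0, 1.0))
        assert r.verdict == DOMINATED

    @given(dc=hs.floats(-5000, 5000), dq=hs.floats(0.01, 2.0),
           wtp=hs.floats(0.0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_nmb_difference_agrees_with_icur_rule(self, dc, dq, wtp):
        """For positive incremental QALYs, a positive incremental NMB is
        equivalent to the ICUR lying below the threshold."""
        assume(abs(wtp * dq - dc) > 1e-6 * max(1.0, wtp))
        d_nmb = (net_monetary_benefit(wtp, 1000.0 + dc, 2.0 + dq)
                 - net_monetary_benefit(wtp, 1000.0, 2.0))
        assert (d_nmb > 0) == (dc / dq < wtp)

    def test_nmb_endpoints(self):
        assert net_monetary_benefit(0.0, 500.0, 2.0) == -500.0
        assert net_monetary_benefit(25000.0, 25000.0, 1.0) == 0.0


class TestPerspectives:
    def test_societal_total_nests_healthcare_total(self, results):
        for strat in ("naive", "experienced"):
            hc = results.outcome(strat, "HEALTHCARE_SECTOR").total_cost
            soc = results.outcome(strat, "SOCIETAL").total_cost
            assert soc >= hc

    def test_category_additivity(self, results):
        out = results.outcome("naive", "SOCIETAL")
        assert out.total_cost == pytest.approx(
            sum(out.cost_by_category.values()), abs=1e-9)
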