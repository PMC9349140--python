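"""Markov engine: transition matrices, cohort traces, occupancy summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from mscua import (ValidationError, aggregate_to_four_states,
                   build_transition_matrix, occupancy_summary,
                   run_cohort_trace)
from mscua import states as st
from mscua.engine import TransitionParams

from conftest import flat_mortality, make_strategy


class TestTransitionMatrix:
    def test_rows_stochastic_and_dead_absorbing(self, demo):
        tp = TransitionParams(p_relapse_by_cycle=0.3,
                              p_remission_given_relapse=0.2,
                              p_switch_given_relapse=0.1)
        P = build_transition_matrix(tp, flat_mortality(0.05), demo, cycle=3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        expected_dead = np.zeros(st.N_STATES)
        expected_dead[st.DEAD] = 1.0
        assert np.array_equal(P[st.DEAD], expected_dead)

    def test_remission_gets_20pct_of_relapse_survivors(self, demo):
        tp = TransitionParams(p_relapse_by_cycle=0.3,
                              p_remission_given_relapse=0.20)
        q = 0.05
        P = build_transition_matrix(tp, flat_mortality(q), demo, cycle=1)
        assert P[st.RELAPSE_TERI, st.REMISSION_TERI] == pytest.approx(
            0.20 * (1 - q), abs=1e-15)

    @pytest.mark.parametrize("cycle,allows,expected", [
        (1, True, 0.0),                 # no switching in the first cycle
        (2, True, 0.10 * 0.8),          # 10% of non-remitting survivors
        (5, False, 0.0),                # experienced strategy never switches
    ])
    def test_switch_timing_and_strategy_gate(self, demo, cycle, allows,
                                             expected):
        tp = TransitionParams(p_relapse_by_cycle=0.3,
                              p_remission_given_relapse=0.2,
                              p_switch_given_relapse=0.10)
        P = build_transition_matrix(tp, flat_mortality(0.0), demo,
                                    cycle=cycle, allows_switch=allows)
        switched_mass = P[st.RELAPSE_TERI,
                          [st.RELAPSE_SWITCHED, st.REMISSION_SWITCHED]].sum()
        assert switched_mass == pytest.approx(expected, abs=1e-15)

    def test_mortality_is_sex_blended_at_current_age(self, demo):
        import pandas as pd
        from mscua import MortalityTable
        rows = []
        for a in range(25, 60):
            rows.append({"age": a, "sex": "F", "p_death": 0.01})
            rows.append({"age": a, "sex": "M", "p_death": 0.03})
        mort = MortalityTable(pd.DataFrame(rows))
        tp = TransitionParams(p_relapse_by_cycle=0.0)
        P = build_transition_matrix(tp, mort, demo, cycle=1)
        expected = 0.7871 * 0.01 + (1 - 0.7871) * 0.03
        assert P[st.CONTROLLED_TERI, st.DEAD] == pytest.approx(expected)

    def test_age_outside_table_raises(self, demo):
        tp = TransitionParams(p_relapse_by_cycle=0.1)
        with pytest.raises(ValidationError, match="outside the mortality"):
            build_transition_matrix(tp, flat_mortality(0.0, ages=range(60, 70)),
                                    demo, cycle=1)

    def test_invalid_probability_names_parameter(self):
        with pytest.raises(ValidationError, match="p_remission_given_relapse"):
            TransitionParams(p_relapse_by_cycle=0.1,
                             p_remission_given_relapse=1.2)


class TestCohortTrace:
    def test_no_event_limit_keeps_cohort_controlled(self):
        trace = run_cohort_trace(make_strategy(q=0.0, p_relapse=0.0),
                                 n0=1000, n_cycles=7)
        assert np.allclose(trace.occupancy[:, st.CONTROLLED_TERI], 1000.0)
        assert trace.accrual[:, st.CONTROLLED_TERI].sum() == pytest.approx(
            7000.0)

    def test_certain_death_gives_half_cycle_credit(self):
        trace = run_cohort_trace(make_strategy(q=1.0), n0=1000, n_cycles=1)
        assert trace.accrual[0].sum() == pytest.approx(500.0)
        assert trace.occupancy[1, st.DEAD] == pytest.approx(1000.0)

    def test_trace_matches_hand_built_matrix_powers(self):
        # 3-live-state chain with q=0.1, p_relapse=0.3, p_remission=0.2,
        # no switching; the expected matrix is written out by hand.
        strat = make_strategy(q=0.1, p_relapse=0.3, p_remission=0.2,
                              allows_switch=False)
        P = np.zeros((6, 6))
        P[0, 0], P[0, 1], P[0, 5] = 0.9 * 0.7, 0.9 * 0.3, 0.1
        P[1, 1], P[1, 2], P[1, 5] = 0.9 * 0.8, 0.9 * 0.2, 0.1
        P[2, 1], P[2, 2], P[2, 5] = 0.9 * 0.3, 0.9 * 0.7, 0.1
        P[5, 5] = 1.0
        x0 = np.zeros(6)
        x0[0] = 1000.0
        trace = run_cohort_trace(strat, n0=1000, n_cycles=3)
        for t in range(1, 4):
            expected = x0 @ np.linalg.matrix_power(P, t)
            assert np.allclose(trace.occupancy[t], expected, atol=1e-12)

    @given(q=hs.floats(0.0, 0.9), p_rel=hs.floats(0.0, 1.0),
           p_rem=hs.floats(0.0, 1.0), p_sw=hs.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_monotone_deaths(self, q, p_rel, p_rem, p_sw):
        strat = make_strategy(q=q, p_relapse=p_rel, p_remission=p_rem,
                              p_switch=p_sw)
        trace = run_cohort_trace(strat, n0=1000, n_cycles=7)
        assert np.allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)
        dead = trace.occupancy[:, st.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(trace.occupancy >= -1e-12)
        assert np.all(trace.accrual >= -1e-12)

    def test_deaths_approximately_two_and_three_per_1000(self, results):
        """Cumulative mortality at the study conditions: ~2 naïve and ~3
        experienced of 1000 (mean dead-state occupancy across cycles)."""
        occ_n = results.occupancy_table("naive")
        occ_e = results.occupancy_table("experienced")
        assert occ_n.loc["DEAD", "mean"] == pytest.approx(2, abs=1)
        assert occ_e.loc["DEAD", "mean"] == pytest.approx(3, abs=1)


class TestSummaries:
    def test_constant_occupancy_summary(self):
        trace = run_cohort_trace(make_strategy(), n0=300, n_cycles=5)
        summ = occupancy_summary(trace)
        assert summ.loc["CONTROLLED_TERI", "mean"] == pytest.approx(300.0)
        assert summ.loc["CONTROLLED_TERI", "sd"] == pytest.approx(0.0)
        assert summ["share"].sum() == pytest.approx(1.0)

    def test_two_point_population_sd(self):
        # occupancies {200, 400} -> mean 300, population SD 100
        trace = run_cohort_trace(make_strategy(), n0=1000, n_cycles=2)
        trace.occupancy[1, st.CONTROLLED_TERI] = 200.0
        trace.occupancy[2, st.CONTROLLED_TERI] = 400.0
        summ = occupancy_summary(trace)
        assert summ.loc["CONTROLLED_TERI", "mean"] == pytest.approx(300.0)
        assert summ.loc["CONTROLLED_TERI", "sd"] == pytest.approx(100.0)

    def test_four_state_aggregation_preserves_totals(self):
        strat = make_strategy(q=0.05, p_relapse=0.4, p_remission=0.3,
                              p_switch=0.2)
        trace = run_cohort_trace(strat, n0=1000, n_cycles=7)
        agg = aggregate_to_four_states(trace)
        assert np.allclose(agg.sum(axis=1), 1000.0, atol=1e-9)
        relapse_total = (trace.occupancy[:, st.RELAPSE_TERI]
                         + trace.occupancy[:, st.RELAPSE_SWITCHED])
        assert np.allclose(agg["RELAPSE"], relapse_total)

    def test_empty_switched_arm_equals_teri_arm(self):
        strat = make_strategy(q=0.01, p_relapse=0.3, allows_switch=False)
        trace = run_cohort_trace(strat, n0=1000, n_cycles=7)
        agg = aggregate_to_four_states(trace)
        assert np.allclose(agg["RELAPSE"],
                           trace.occupancy[:, st.RELAPSE_TERI])
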