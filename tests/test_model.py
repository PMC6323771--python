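"""Strategy encodings, transition matrices and the cohort engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gist_cua import (
    HealthState,
    StrategyDefinition,
    Treatment,
    combine_mortality,
    make_strategy,
    monthly_drug_cost,
    overall_survival,
    run_cohort,
    state_rewards,
    transition_matrix,
)
from gist_cua.model import DAYS_PER_MONTH, N_STATES, monthly_background_mortality

S = HealthState
ALL_OPTIONS = ("1", "4", "2.1", "3.1", "2.2", "3.2")


class TestStrategies:
    def test_baseline_option(self):
        s = make_strategy("1")
        assert s.adjuvant_months == 0
        assert s.recurrence_after_adjuvant == (Treatment.IMATINIB, Treatment.BSC)

    def test_three_year_imatinib_then_bsc(self):
        s = make_strategy("2.2")
        assert s.adjuvant_months == 36
        assert s.recurrence_during_adjuvant == (Treatment.BSC,)
        assert s.recurrence_after_adjuvant == (Treatment.IMATINIB, Treatment.BSC)

    def test_one_year_with_sunitinib_lines(self):
        s = make_strategy("3.1")
        assert s.adjuvant_months == 12
        assert s.recurrence_during_adjuvant == (Treatment.SUNITINIB, Treatment.BSC)
        assert s.recurrence_after_adjuvant == (
            Treatment.IMATINIB,
            Treatment.SUNITINIB,
            Treatment.BSC,
        )

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="unknown option"):
            make_strategy("5")

    def test_sequences_must_end_in_bsc(self):
        with pytest.raises(ValueError, match="end in BSC"):
            StrategyDefinition("x", 0, (), (Treatment.IMATINIB,))

    def test_progression_successors(self):
        s32 = make_strategy("3.2")
        assert s32.successor(Treatment.IMATINIB) is Treatment.SUNITINIB
        assert s32.successor(Treatment.SUNITINIB) is Treatment.BSC
        assert s32.successor(Treatment.BSC) is None
        assert make_strategy("1").successor(Treatment.IMATINIB) is Treatment.BSC


class TestDrugCostsAndRewards:
    def test_imatinib_monthly_cost_truncates_to_published_value(self):
        assert monthly_drug_cost(3659.40, 1, DAYS_PER_MONTH) == 111_306

    def test_trivial_month(self):
        assert monthly_drug_cost(1.0, 1, 30) == 30

    def test_continuous_sunitinib_dosing_exceeds_published_cycle_cost(self):
        # 4 x 12.5 mg capsules every day would cost more than the published
        # 82,173 THB/month, which embeds the 4-weeks-on / 2-weeks-off schedule
        assert monthly_drug_cost(1100.53, 4, DAYS_PER_MONTH) == 133_897

    def test_offdrug_monitoring_cost(self, params):
        r = state_rewards(make_strategy("1"), params)
        assert r.costs[S.NoRec_NoAdj] == pytest.approx(2758 + 0.3 * (296 + 109 + 99))
        assert r.costs[S.NoRec_NoAdj] == pytest.approx(2909.2)

    def test_on_adjuvant_cost_stacks_drug_monitoring_ae_and_visits(self, params):
        r = state_rewards(make_strategy("2.2"), params)
        assert r.costs[S.NoRec_OnAdj] == pytest.approx(111_306 + 1477 + 570 + 0.6 * 504)

    def test_recurrence_line_costs(self, params):
        r = state_rewards(make_strategy("1"), params)
        assert r.costs[S.Rec_Imatinib] == pytest.approx(111_306 + 4213 + 504)
        assert r.costs[S.Rec_Sunitinib] == pytest.approx(82_173 + 7141 + 504)
        assert r.costs[S.Rec_BSC] == pytest.approx(4247 + 504)

    def test_utilities(self, params):
        r = state_rewards(make_strategy("2.2"), params)
        assert r.utilities[S.NoRec_OnAdj] == 0.79
        assert r.utilities[S.NoRec_NoAdj] == 0.89
        assert r.utilities[S.NoRec_Completed] == 0.89
        assert (
            r.utilities[S.Rec_Imatinib],
            r.utilities[S.Rec_Sunitinib],
            r.utilities[S.Rec_BSC],
        ) == (0.66, 0.58, 0.42)

    def test_dead_state_carries_nothing(self, params):
        r = state_rewards(make_strategy("1"), params)
        assert r.costs[S.Dead] == 0.0
        assert r.utilities[S.Dead] == 0.0

    def test_price_override_rescales_imatinib_everywhere(self, params):
        base = state_rewards(make_strategy("2.2"), params)
        half = state_rewards(make_strategy("2.2"), params, price_override=3659.40 / 2)
        assert half.costs[S.NoRec_OnAdj] == pytest.approx(base.costs[S.NoRec_OnAdj] - 111_306 / 2)
        assert half.costs[S.Rec_Imatinib] == pytest.approx(base.costs[S.Rec_Imatinib] - 111_306 / 2)
        assert half.costs[S.Rec_Sunitinib] == base.costs[S.Rec_Sunitinib]


class TestCombineMortality:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.0, 0.001, 0.001), (0.0017, 0.0008, 0.0024986), (1.0, 0.3, 1.0)],
    )
    def test_independent_competing_risks(self, a, b, expected):
        assert combine_mortality(a, b) == pytest.approx(expected, abs=1e-7)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded_below_by_max(self, a, b):
        c = combine_mortality(a, b)
        assert c == pytest.approx(combine_mortality(b, a), rel=1e-12)
        assert c >= max(a, b) - 1e-15
        assert c <= 1.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("option", ALL_OPTIONS)
    def test_rows_stochastic_over_full_horizon(self, params, life_table, option):
        strat = make_strategy(option)
        for cycle in (1, 6, 7, 12, 13, 36, 37, 60, 85, 120, 480):
            m = transition_matrix(strat, params, life_table, cycle)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()

    def test_option1_cycle6_row_hand_assembled(self, params, life_table):
        m = transition_matrix(make_strategy("1"), params, life_table, 6)
        bg = monthly_background_mortality(life_table, 60.0)
        row = m[S.NoRec_NoAdj]
        assert row[S.Rec_Imatinib] == pytest.approx(0.0205)
        assert row[S.Dead] == pytest.approx(combine_mortality(0.0017, bg), rel=1e-12)
        assert row[S.NoRec_NoAdj] == pytest.approx(1 - 0.0205 - combine_mortality(0.0017, bg))
        assert row[[S.NoRec_OnAdj, S.NoRec_Completed, S.Rec_Sunitinib, S.Rec_BSC]].sum() == 0

    def test_bsc_row_treatment_specific_death_only_when_switched(self, params, life_table):
        """Under the treatment-specific-only reading, BSC exits are death alone."""
        spec_reading = params.with_scalars(gist_death_in_recurrence=False)
        m = transition_matrix(make_strategy("1"), spec_reading, life_table, 6)
        bg = monthly_background_mortality(life_table, 60.0)
        row = m[S.Rec_BSC]
        assert row[S.Dead] == pytest.approx(combine_mortality(0.0680, bg), rel=1e-12)
        assert row[S.Rec_BSC] == pytest.approx(1 - row[S.Dead])

    def test_bsc_row_default_adds_banded_gist_death(self, params, life_table):
        m = transition_matrix(make_strategy("1"), params, life_table, 6)
        bg = monthly_background_mortality(life_table, 60.0)
        expected = combine_mortality(combine_mortality(0.0680, 0.0017), bg)
        assert m[S.Rec_BSC, S.Dead] == pytest.approx(expected, rel=1e-12)

    def test_recurrence_routing_depends_on_adjuvant_history(self, params, life_table):
        m = transition_matrix(make_strategy("2.2"), params, life_table, 6)
        # on adjuvant or after early discontinuation: recurrence goes to BSC
        assert m[S.NoRec_OnAdj, S.Rec_BSC] > 0
        assert m[S.NoRec_OnAdj, S.Rec_Imatinib] == 0
        assert m[S.NoRec_Discontinued, S.Rec_BSC] == pytest.approx(0.0205)
        # after completing the course: recurrence goes to imatinib
        m_late = transition_matrix(make_strategy("2.2"), params, life_table, 40)
        assert m_late[S.NoRec_Completed, S.Rec_Imatinib] == pytest.approx(0.0056)

    def test_completion_cycle_moves_survivors_to_completed(self, params, life_table):
        m = transition_matrix(make_strategy("2.2"), params, life_table, 36)
        assert m[S.NoRec_OnAdj, S.NoRec_OnAdj] == 0.0
        assert m[S.NoRec_OnAdj, S.NoRec_Completed] > 0.9

    def test_cycle_must_be_positive(self, params, life_table):
        with pytest.raises(ValueError):
            transition_matrix(make_strategy("1"), params, life_table, 0)


class TestRunCohort:
    def test_zeroed_hazards_freeze_the_cohort(self, params, life_table):
        frozen = params.with_values(
            p_rec_yr1=0.0, p_rec_yr3=0.0, p_rec_yr5=0.0,
            p_death_gist_yr1=0.0, p_death_gist_yr3=0.0, p_death_gist_yr5=0.0,
            p_death_gist_yr7=0.0, p_death_gist_yr9=0.0,
        ).with_scalars(background_mortality=False)
        trace = run_cohort(make_strategy("1"), frozen, life_table, 24)
        assert np.allclose(trace.occupancy[:, S.NoRec_NoAdj], 1.0)

    def test_matches_explicit_matrix_power_oracle(self, params, life_table):
        """A 3-cycle trace equals the explicit product of cycle matrices."""
        for option in ("1", "2.2", "3.1"):
            strat = make_strategy(option)
            trace = run_cohort(strat, params, life_table, 3)
            occ = np.zeros(N_STATES)
            occ[S.NoRec_OnAdj if strat.adjuvant_months else S.NoRec_NoAdj] = 1.0
            for cycle in range(1, 4):
                occ = occ @ transition_matrix(strat, params, life_table, cycle)
                assert np.allclose(trace.occupancy[cycle], occ, atol=1e-12)

    @pytest.mark.parametrize("option", ALL_OPTIONS)
    def test_conservation_and_dead_monotonicity(self, params, life_table, option):
        trace = run_cohort(make_strategy(option), params, life_table, 480)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (trace.occupancy >= -1e-15).all()
        dead = trace.occupancy[:, S.Dead]
        assert (np.diff(dead) >= -1e-12).all()

    def test_conservation_under_perturbed_parameters(self, params, life_table):
        """Occupancy stays conserved for random valid parameter sets."""
        from gist_cua.uncertainty import psa_draw

        rng = np.random.default_rng(7)
        for _ in range(5):
            drawn = psa_draw(params, rng)
            trace = run_cohort(make_strategy("3.2"), drawn, life_table, 120)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert (np.diff(trace.occupancy[:, S.Dead]) >= -1e-12).all()

    def test_neutralised_adjuvant_equals_no_adjuvant(self, params, life_table):
        """HR 1, no discontinuation, identical recurrence pathway: option 2.2's
        trace must equal option 1's with the no-recurrence labels merged."""
        neutral = params.with_values(
            hr_adj_3yr=1.0, p_disc_3yr_m1_6=0.0, p_disc_3yr_m7_36=0.0
        )
        like_one = StrategyDefinition(
            option_id="2.2-neutral",
            adjuvant_months=36,
            recurrence_during_adjuvant=(Treatment.IMATINIB, Treatment.BSC),
            recurrence_after_adjuvant=(Treatment.IMATINIB, Treatment.BSC),
        )
        t_adj = run_cohort(like_one, neutral, life_table, 120)
        t_base = run_cohort(make_strategy("1"), neutral, life_table, 120)
        norec = [S.NoRec_NoAdj, S.NoRec_OnAdj, S.NoRec_Completed, S.NoRec_Discontinued]
        merged_adj = t_adj.occupancy[:, norec].sum(axis=1)
        merged_base = t_base.occupancy[:, norec].sum(axis=1)
        assert np.allclose(merged_adj, merged_base, atol=1e-12)
        for state in (S.Rec_Imatinib, S.Rec_Sunitinib, S.Rec_BSC, S.Dead):
            assert np.allclose(t_adj.occupancy[:, state], t_base.occupancy[:, state], atol=1e-12)

    def test_longer_or_stronger_adjuvant_never_loses_life_expectancy(self, base_results):
        ly = {k: r.ly_disc for k, r in base_results.items()}
        assert ly["2.1"] >= ly["1"]
        assert ly["2.2"] >= ly["2.1"]
        assert ly["3.2"] >= ly["3.1"] >= ly["1"]

    def test_residual_mass_reported(self, params, life_table):
        trace = run_cohort(make_strategy("1"), params, life_table, 480)
        assert 0.0 <= trace.residual_alive < 0.01

    def test_trace_export_schema(self, params, life_table, tmp_path):
        import pandas as pd

        trace = run_cohort(make_strategy("1"), params, life_table, 12)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert len(df) == 13
        assert df["age"].iloc[0] == 60.0


class TestOverallSurvival:
    def test_starts_at_one_and_never_increases(self, params, life_table):
        trace = run_cohort(make_strategy("2.2"), params, life_table, 240)
        os = overall_survival(trace)
        assert os["proportion_alive"].iloc[0] == 1.0
        assert (os["proportion_alive"].diff().dropna() <= 1e-12).all()

    def test_absorbing_toy(self, params, life_table):
        lethal = params.with_values(p_rec_yr1=0.0, p_death_gist_yr1=1.0)
        trace = run_cohort(make_strategy("1"), lethal, life_table, 2)
        os = overall_survival(trace)
        assert os["proportion_alive"].iloc[1] == pytest.approx(0.0)

    def test_adjuvant_improves_three_year_survival(self, params, life_table):
        t1 = run_cohort(make_strategy("1"), params, life_table, 48)
        t22 = run_cohort(make_strategy("2.2"), params, life_table, 48)
        s1 = overall_survival(t1)["proportion_alive"].iloc[36]
        s22 = overall_survival(t22)["proportion_alive"].iloc[36]
        assert s22 > s1
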