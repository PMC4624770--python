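"""Cohort engine: decision tree, Markov cycles, discounting, correction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sadcea.cohort import (
    CohortResult,
    StateOccupancy,
    Timeline,
    evaluate_cohort,
    qaly_segment,
    run_decision_tree_year,
    run_markov_years,
)
from sadcea.parameters import InvalidParameterError

U_REC, U_SAD = 0.866, 0.659
C_REC, C_SAD = 645.0, 1037.0

probability = st.floats(min_value=0.0, max_value=1.0)


def tree(p, rel, cost_nonrec=0.0, cost_rec=0.0, **kw):
    return run_decision_tree_year(
        p, rel, cost_nonrec, cost_rec, U_REC, U_SAD, C_REC, C_SAD, **kw
    )


class TestQALYSegment:
    def test_constant_utility_one_year(self):
        assert qaly_segment(0.7, 0.7, 1.0) == pytest.approx(0.7)

    def test_treatment_ramp(self):
        expected = (0.659 + 0.866) / 2 * 12 / 52
        assert qaly_segment(0.659, 0.866, 12 / 52) == pytest.approx(expected)
        assert expected == pytest.approx(0.17596, abs=5e-6)

    def test_one_year_discounted_once(self):
        assert qaly_segment(0.7, 0.7, 1.0, 0.035, 1.0) == pytest.approx(0.7 / 1.035)

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            qaly_segment(0.7, 0.7, -1.0)


class TestDecisionTree:
    def test_no_recovery_cohort(self):
        occupancy, cost, qaly = tree(0.0, 0.4, cost_nonrec=300.0)
        assert (occupancy.well, occupancy.sad) == (0.0, 1.0)
        assert qaly == pytest.approx(U_SAD * (12 / 52 + 1.0))
        assert cost == pytest.approx(300.0 + C_SAD)

    def test_full_recovery_no_relapse(self):
        occupancy, cost, qaly = tree(1.0, 0.0)
        assert occupancy.well == 1.0
        assert qaly == pytest.approx((U_SAD + U_REC) / 2 * 12 / 52 + U_REC)
        assert cost == pytest.approx(C_REC)

    def test_relapse_product_rule(self):
        occupancy, _, _ = tree(0.5, 0.4169)
        assert occupancy.well == pytest.approx(0.29155)

    def test_relapsers_credited_between_the_states(self):
        # full relapse: post-treatment utility is the midpoint of the states
        _, cost, qaly = tree(1.0, 1.0)
        assert qaly == pytest.approx((U_SAD + U_REC) / 2 * 12 / 52 + (U_SAD + U_REC) / 2)
        assert cost == pytest.approx((C_REC + C_SAD) / 2)

    def test_recoverers_pay_maintenance_even_if_they_relapse(self):
        _, cost, _ = tree(1.0, 1.0, cost_nonrec=100.0, cost_rec=150.0)
        assert cost == pytest.approx(150.0 + (C_REC + C_SAD) / 2)

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvalidParameterError):
            tree(1.4, 0.0)


class TestMarkov:
    def test_absorbing_no_flow_chain(self):
        occupancy, cost, qaly = run_markov_years(
            StateOccupancy(1.0, 0.0), 0.0, 0.0, 4, U_REC, U_SAD, C_REC, C_SAD, 0.0
        )
        assert occupancy.well == 1.0
        assert qaly == pytest.approx(4 * U_REC)
        assert cost == pytest.approx(4 * C_REC)

    def test_geometric_compounding_oracle(self):
        occupancy, _, _ = run_markov_years(
            StateOccupancy(0.0, 1.0), 0.0377, 0.0, 4, U_REC, U_SAD, C_REC, C_SAD, 0.0
        )
        assert occupancy.well == pytest.approx(1 - (1 - 0.0377) ** 4, abs=1e-12)

    def test_stationary_distribution_is_invariant(self):
        p_rec, p_rel = 0.0377, 0.0409
        w_star = p_rec / (p_rec + p_rel)
        occupancy, _, _ = run_markov_years(
            StateOccupancy(w_star, 1 - w_star), p_rec, p_rel, 6, U_REC, U_SAD, C_REC, C_SAD, 0.0
        )
        assert occupancy.well == pytest.approx(w_star, abs=1e-12)

    def test_closed_form_without_correction_or_discounting(self):
        """Pure decay chain: occupancy-weighted sums have a geometric closed
        form, an oracle independent of the engine's loop."""
        q, n = 0.3, 5
        _, cost, qaly = run_markov_years(
            StateOccupancy(1.0, 0.0), 0.0, q, n, U_REC, U_SAD, C_REC, C_SAD,
            discount_rate=0.0, half_cycle_correction=False,
        )
        geo = sum((1 - q) ** k for k in range(1, n + 1))
        assert qaly == pytest.approx(n * U_SAD + (U_REC - U_SAD) * geo, abs=1e-12)
        assert cost == pytest.approx(n * C_SAD + (C_REC - C_SAD) * geo, abs=1e-12)

    def test_half_cycle_correction_averages_endpoints(self):
        # one cycle from (1, 0) with certain relapse: credited occupancy 0.5
        _, _, qaly = run_markov_years(
            StateOccupancy(1.0, 0.0), 0.0, 1.0, 1, U_REC, U_SAD, C_REC, C_SAD, 0.0
        )
        assert qaly == pytest.approx(0.5 * (U_REC + U_SAD))

    def test_discounting_offsets(self):
        r = 0.035
        _, _, qaly = run_markov_years(
            StateOccupancy(1.0, 0.0), 0.0, 0.0, 3, U_REC, U_SAD, C_REC, C_SAD, r
        )
        assert qaly == pytest.approx(U_REC * sum((1 + r) ** -k for k in (1, 2, 3)))


class TestEvaluateCohort:
    def run(self, **kw):
        defaults = dict(
            p_recover=0.4,
            relapse_y1=0.2,
            cost_nonrecovered=100.0,
            cost_recovered=150.0,
            p_recover_annual=0.0377,
            p_relapse_annual=0.0409,
            u_recovered=U_REC,
            u_sad=U_SAD,
            annual_cost_recovered=C_REC,
            annual_cost_sad=C_SAD,
            discount_rate=0.035,
            timeline=Timeline(),
        )
        defaults.update(kw)
        return evaluate_cohort(**defaults)

    def test_equal_utility_zero_flow_closed_form(self):
        u = 0.7
        result = self.run(
            p_recover=0.0, relapse_y1=0.0, p_recover_annual=0.0, p_relapse_annual=0.0,
            u_recovered=u, u_sad=u, discount_rate=0.0,
            cost_nonrecovered=0.0, cost_recovered=0.0,
        )
        assert result.discounted_qaly == pytest.approx(u * (12 / 52 + 5), abs=1e-9)
        assert result.discounted_cost == pytest.approx(5 * C_SAD)

    def test_two_cycle_toy_against_hand_oracle(self):
        """Round-number toy recomputed step by step with independent
        arithmetic (spreadsheet style)."""
        p, rel = 0.5, 0.2
        u_r, u_s, c_r, c_s = 0.9, 0.6, 200.0, 400.0
        p_rec, p_rel, r = 0.1, 0.3, 0.05

        # year 1
        well1 = p * (1 - rel)                     # 0.4
        relapsed = p * rel                        # 0.1
        qaly = p * (u_s + u_r) / 2 * (12 / 52) + (1 - p) * u_s * (12 / 52)
        qaly += well1 * u_r + relapsed * (u_r + u_s) / 2 + (1 - p) * u_s
        cost = p * 150.0 + (1 - p) * 100.0
        cost += well1 * c_r + relapsed * (c_r + c_s) / 2 + (1 - p) * c_s
        # cycle 1
        well2 = well1 * (1 - p_rel) + (1 - well1) * p_rec          # 0.34
        mid = (well1 + well2) / 2
        qaly += (mid * u_r + (1 - mid) * u_s) / 1.05
        cost += (mid * c_r + (1 - mid) * c_s) / 1.05
        # cycle 2
        well3 = well2 * (1 - p_rel) + (1 - well2) * p_rec          # 0.304
        mid = (well2 + well3) / 2
        qaly += (mid * u_r + (1 - mid) * u_s) / 1.05**2
        cost += (mid * c_r + (1 - mid) * c_s) / 1.05**2

        result = self.run(
            p_recover=p, relapse_y1=rel, u_recovered=u_r, u_sad=u_s,
            annual_cost_recovered=c_r, annual_cost_sad=c_s,
            p_recover_annual=p_rec, p_relapse_annual=p_rel, discount_rate=r,
            timeline=Timeline(markov_cycles=2),
        )
        assert result.discounted_qaly == pytest.approx(qaly, abs=1e-10)
        assert result.discounted_cost == pytest.approx(cost, abs=1e-10)
        assert result.fraction_well_at_horizon == pytest.approx(well3, abs=1e-12)

    def test_discounting_reduces_totals(self):
        undiscounted = self.run(discount_rate=0.0)
        discounted = self.run(discount_rate=0.035)
        assert discounted.discounted_qaly < undiscounted.discounted_qaly
        assert undiscounted.discounted_qaly <= U_REC * (12 / 52 + 5)

    @given(p=probability, rel=probability, p_rec=probability, p_rel=probability)
    @settings(max_examples=150, deadline=None)
    def test_occupancy_conservation_and_bounds(self, p, rel, p_rec, p_rel):
        occupancy, _, _ = tree(p, rel)
        assert occupancy.well + occupancy.sad == pytest.approx(1.0, abs=1e-12)
        result = self.run(
            p_recover=p, relapse_y1=rel, p_recover_annual=p_rec, p_relapse_annual=p_rel
        )
        assert 0.0 <= result.fraction_well_at_horizon <= 1.0
        assert 0.0 <= result.discounted_qaly <= U_REC * (12 / 52 + 5)

    @given(
        p1=st.floats(min_value=0.0, max_value=0.98),
        dp=st.floats(min_value=1e-6, max_value=0.02),
        rel=probability,
    )
    @settings(max_examples=150, deadline=None)
    def test_qaly_monotone_in_recovery(self, p1, dp, rel):
        low = self.run(p_recover=p1, relapse_y1=rel)
        high = self.run(p_recover=p1 + dp, relapse_y1=rel)
        assert high.discounted_qaly >= low.discounted_qaly

    @given(
        rel1=st.floats(min_value=0.0, max_value=0.98),
        dr=st.floats(min_value=1e-6, max_value=0.02),
        p=probability,
    )
    @settings(max_examples=150, deadline=None)
    def test_qaly_nonincreasing_in_relapse(self, rel1, dr, p):
        low = self.run(p_recover=p, relapse_y1=rel1)
        high = self.run(p_recover=p, relapse_y1=rel1 + dr)
        assert high.discounted_qaly <= low.discounted_qaly + 1e-12


class TestValidation:
    def test_occupancy_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            StateOccupancy(0.6, 0.6)

    def test_timeline_bounds(self):
        with pytest.raises(InvalidParameterError):
            Timeline(treatment_weeks=0)
        with pytest.raises(InvalidParameterError):
            Timeline(markov_cycles=-1)
        assert Timeline(markov_cycles=0).horizon_years_post_treatment == 1
        assert Timeline().total_years == pytest.approx(12 / 52 + 5)

    def test_cohort_result_bounds(self):
        with pytest.raises(InvalidParameterError):
            CohortResult(-1.0, 2.0, 0.5)
        with pytest.raises(InvalidParameterError):
            CohortResult(1.0, 2.0, 1.5)
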