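"""Parameter derivations, distribution sampling and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sadcea
from sadcea.parameters import (
    DistributionSpec,
    InterventionDefinition,
    InvalidParameterError,
    ModelParameters,
    UnsupportedDistributionError,
    annual_to_multi_year_prob,
    beta_mean_from_counts,
    categorical_from_groups,
    drug_relapse_year1,
    gamma_from_mean_se,
    lognormal_params_from_ci,
    multi_year_to_annual_prob,
    point,
    psych_relapse_year1,
)


class TestDerivations:
    @pytest.mark.parametrize(
        "alpha,beta,expected,places",
        [
            (4572, 707, 0.866, 3),  # utility of recovery
            (1, 1, 0.5, 12),
            (65, 111, 0.36932, 5),  # 12-year recovery probability
        ],
    )
    def test_beta_mean(self, alpha, beta, expected, places):
        assert beta_mean_from_counts(alpha, beta) == pytest.approx(expected, abs=10**-places / 2)

    @pytest.mark.parametrize(
        "mean,se,shape,scale",
        [(645, 93, 48.10, 13.41), (1037, 209, 24.62, 42.12)],
    )
    def test_gamma_moment_matching(self, mean, se, shape, scale):
        got_shape, got_scale = gamma_from_mean_se(mean, se)
        assert got_shape == pytest.approx(shape, abs=5e-3)
        assert got_scale == pytest.approx(scale, abs=5e-3)
        # moment matching is exact in closed form
        assert got_shape * got_scale == pytest.approx(mean, rel=1e-12)
        assert got_shape * got_scale**2 == pytest.approx(se**2, rel=1e-12)

    @pytest.mark.parametrize(
        "p_multi,years,expected",
        [
            (65 / 176, 12, 0.0377),  # annual recovery, years 2-5
            (26 / 66, 12, 0.0409),  # annual relapse, years 2-5
            (0.0, 7, 0.0),
        ],
    )
    def test_multi_year_to_annual(self, p_multi, years, expected):
        assert multi_year_to_annual_prob(p_multi, years) == pytest.approx(expected, abs=5e-5)

    def test_drug_relapse_midpoint(self):
        assert drug_relapse_year1((107, 293), (222, 170)) == pytest.approx(0.4169, abs=5e-5)
        assert drug_relapse_year1((1, 1), (1, 1)) == 0.5
        assert drug_relapse_year1((107, 293), (107, 293)) == pytest.approx(0.2675, abs=5e-5)

    def test_psych_relapse(self):
        assert psych_relapse_year1(0.4169, 3.0) == pytest.approx(0.1390, abs=5e-5)
        assert psych_relapse_year1(0.37, 1.0) == 0.37
        assert psych_relapse_year1(0.9, 0.5) == 1.0  # clipped

    @pytest.mark.parametrize(
        "func,args",
        [
            (beta_mean_from_counts, (0, 5)),
            (beta_mean_from_counts, (5, -1)),
            (gamma_from_mean_se, (0, 93)),
            (gamma_from_mean_se, (645, 0)),
            (multi_year_to_annual_prob, (1.0, 12)),
            (multi_year_to_annual_prob, (0.5, 0)),
            (psych_relapse_year1, (0.5, 0.0)),
            (psych_relapse_year1, (1.5, 2.0)),
        ],
    )
    def test_invalid_inputs_rejected(self, func, args):
        with pytest.raises(InvalidParameterError):
            func(*args)

    def test_lognormal_ci_midpoint(self):
        mu, sigma = lognormal_params_from_ci(0.73, 12.39)
        assert math.exp(mu) == pytest.approx(3.007, abs=2e-3)  # close to the stated mean 3.00
        assert sigma == pytest.approx((math.log(12.39) - math.log(0.73)) / 3.92, rel=1e-12)


class TestConversionProperties:
    @given(
        p=st.floats(min_value=0.0, max_value=0.999),
        years=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p, years):
        annual = multi_year_to_annual_prob(p, years)
        assert 0.0 <= annual < 1.0
        assert annual_to_multi_year_prob(annual, years) == pytest.approx(p, abs=1e-12)

    @given(
        p1=st.floats(min_value=0.0, max_value=0.99),
        delta=st.floats(min_value=1e-6, max_value=0.009),
        years=st.integers(min_value=2, max_value=30),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_multi(self, p1, delta, years):
        assert multi_year_to_annual_prob(p1 + delta, years) > multi_year_to_annual_prob(p1, years)


class TestSampling:
    N = 100_000

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("beta-counts", {"alpha": 65, "beta": 111}),
            DistributionSpec("gamma-mean-se", {"mean": 645.0, "se": 93.0}),
            DistributionSpec("log-normal-ci", {"mean": 3.0, "ci_low": 0.73, "ci_high": 12.39}),
            DistributionSpec("normal-mean-var", {"mean": 75.0, "var": 22.5**2}),
            DistributionSpec(
                "midpoint-of-two-betas",
                {"alpha1": 107, "beta1": 293, "alpha2": 222, "beta2": 170},
            ),
        ],
        ids=lambda s: s.family,
    )
    def test_sample_mean_matches_closed_form(self, spec, rng):
        draws = np.asarray(spec.sample(rng, self.N), dtype=float)
        sem = draws.std() / math.sqrt(self.N)
        assert draws.mean() == pytest.approx(spec.mean(), abs=3 * sem)

    def test_point_is_degenerate(self, rng):
        spec = point(0.035)
        assert spec.sample(rng) == 0.035
        assert (spec.sample(rng, 10) == 0.035).all()
        assert spec.mean() == 0.035

    def test_categorical_frequencies(self, rng):
        spec = categorical_from_groups(
            [
                {"prob": 0.65, "values": [4]},
                {"prob": 0.10, "values": [3, 5, 6]},
                {"prob": 0.25, "values": [1, 2]},
            ]
        )
        draws = spec.sample(rng, self.N)
        freq4 = np.mean(draws == 4)
        assert freq4 == pytest.approx(0.65, abs=0.005)
        assert np.mean(draws == 3) == pytest.approx(0.10 / 3, abs=0.005)
        assert spec.mean() == pytest.approx(4 * 0.65 + (3 + 5 + 6) * 0.10 / 3 + (1 + 2) * 0.125)

    def test_categorical_range_groups(self):
        spec = categorical_from_groups(
            [{"prob": 0.8, "values": [14]}, {"prob": 0.2, "range": [10, 13]}]
        )
        probs = dict(zip(spec.params["values"], spec.params["probs"]))
        assert probs[14] == pytest.approx(0.8)
        assert probs[10] == pytest.approx(0.05)
        assert sum(spec.params["probs"]) == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_reproduces_draws(self):
        spec = DistributionSpec("beta-counts", {"alpha": 65, "beta": 111})
        a = spec.sample(np.random.default_rng(5), 100)
        b = spec.sample(np.random.default_rng(5), 100)
        assert (a == b).all()

    def test_unknown_family_rejected(self):
        with pytest.raises(UnsupportedDistributionError):
            DistributionSpec("triangular", {"a": 1})

    @pytest.mark.parametrize(
        "family,params",
        [
            ("beta-counts", {"alpha": -1, "beta": 2}),
            ("gamma-mean-se", {"mean": -5, "se": 1}),
            ("log-normal-ci", {"mean": 3.0, "ci_low": 2.0, "ci_high": 1.0}),
            ("categorical", {"values": [1, 2], "probs": [0.7, 0.2]}),
            ("categorical", {"values": [1, 2], "probs": [-0.5, 1.5]}),
            ("midpoint-of-two-betas", {"alpha1": 0, "beta1": 1, "alpha2": 1, "beta2": 1}),
        ],
    )
    def test_invalid_spec_rejected(self, family, params):
        with pytest.raises(InvalidParameterError):
            DistributionSpec(family, params)


class TestModelParameters:
    def test_packaged_yaml_mirrors_code_defaults(self):
        assert ModelParameters.defaults() == ModelParameters()

    def test_point_estimates_match_published(self, params):
        assert params.relapse_drug_y1_point == pytest.approx(0.4169, abs=5e-5)
        assert params.relapse_psych_y1_point == pytest.approx(0.139, abs=5e-4)
        assert params.recovery_annual_y2_5 == pytest.approx(0.0377, abs=5e-5)
        assert params.relapse_annual_y2_5 == pytest.approx(0.0409, abs=5e-5)
        assert params.relapse_waitlist_y1_value == params.relapse_annual_y2_5

    def test_waitlist_relapse_overridable(self):
        p = ModelParameters(relapse_waitlist_y1=0.1)
        assert p.relapse_waitlist_y1_value == 0.1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"utility_recovered": 0.5, "utility_sad": 0.7},
            {"discount_rate": 1.2},
            {"horizon_years_post_treatment": 0},
            {"annual_cost_sad": -10.0},
            {"relapse_waitlist_y1": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParameters(**kwargs)


class TestInterventionDefinitions:
    def test_packaged_set_is_complete(self, interventions, by_id):
        assert len(interventions) == 28
        assert len(by_id) == 28
        classes = {it.treatment_class for it in interventions}
        assert classes == {
            "pharmacological",
            "individual-psychological",
            "group-psychological",
            "self-help",
            "pill-placebo",
            "wait-list",
        }
        assert sum(it.treatment_class == "pharmacological" for it in interventions) == 11

    def test_placebo_uses_drug_relapse(self, by_id):
        assert by_id["pill_placebo"].relapse_class == "drug"
        with pytest.raises(InvalidParameterError):
            InterventionDefinition("x", "X", "pill-placebo", "psychological")

    def test_waitlist_has_no_cost_profile(self, by_id):
        assert by_id["wait_list"].cost_profile is None
        assert sadcea.full_adherence_cost(by_id["wait_list"]) == 0.0
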