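"""Distribution construction, risk conversion and scenario I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from cryocea.params import (
    DistributionSpec,
    Scenario,
    UncertainParam,
    beta_from_mean_n,
    beta_mean,
    cumulative_to_annual,
    gamma_from_mean_sd,
    load_scenario,
    point,
    rescale_to_mean,
    write_scenario,
)


class TestBetaMean:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (2, 192, 0.01031),  # 2/194: the trial's distant-metastasis rate
            (1, 1, 0.5),
            (8, 186, 0.041237),
        ],
    )
    def test_values(self, a, b, expected):
        spec = DistributionSpec(kind="beta", a=a, b=b)
        assert beta_mean(spec) == pytest.approx(expected, abs=5e-6)

    def test_wrong_kind_raises(self):
        with pytest.raises(TypeError):
            beta_mean(point(0.5))


class TestGammaFromMeanSd:
    @pytest.mark.parametrize(
        "mean, sd, shape, scale",
        [
            (2501.0, 500.0, 25.0200, 99.9600),
            (817.0, 39.0, 438.8488, 1.86169),
        ],
    )
    def test_moment_matching(self, mean, sd, shape, scale):
        spec = gamma_from_mean_sd(mean, sd)
        assert spec.a == pytest.approx(shape, rel=1e-4)
        assert spec.b == pytest.approx(scale, rel=1e-4)

    @given(
        mean=st.floats(1.0, 1e6),
        sd=st.floats(1.0, 1e5),
    )
    @settings(max_examples=50, deadline=None)
    def test_first_two_moments_recovered(self, mean, sd):
        spec = gamma_from_mean_sd(mean, sd)
        assert spec.a * spec.b == pytest.approx(mean, rel=1e-9)
        assert spec.sd() == pytest.approx(sd, rel=1e-9)

    @pytest.mark.parametrize("mean, sd", [(0.0, 1.0), (1.0, 0.0), (-5.0, 2.0)])
    def test_nonpositive_inputs_rejected(self, mean, sd):
        with pytest.raises(ValueError):
            gamma_from_mean_sd(mean, sd)


class TestCumulativeToAnnual:
    def test_linear_matches_published_annualizations(self):
        # 5-year local recurrence 4.3% -> 0.86%/yr; 1.03% at 54 months -> 0.23%/yr
        assert cumulative_to_annual(0.043, 5) == pytest.approx(0.0086)
        assert cumulative_to_annual(0.0103, 4.5) == pytest.approx(0.00229, abs=1e-5)

    @pytest.mark.parametrize("method", ["linear", "exponential"])
    def test_zero_risk(self, method):
        assert cumulative_to_annual(0.0, 7.3, method) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cumulative_to_annual(1.2, 5)
        with pytest.raises(ValueError):
            cumulative_to_annual(0.5, 0.0)

    # by Bernoulli's inequality the constant-hazard conversion dominates the
    # linear one whenever the horizon exceeds one year, and vice versa
    @given(p=st.floats(1e-9, 1.0, exclude_max=True), years=st.floats(0.5, 20))
    @settings(max_examples=200, deadline=None)
    def test_exponential_dominates_linear_beyond_one_year(self, p, years):
        lin = cumulative_to_annual(p, years, "linear")
        expo = cumulative_to_annual(p, years, "exponential")
        if years >= 1.0:
            assert expo >= min(lin, 1.0) - 1e-12
        else:
            assert min(lin, 1.0) >= expo - 1e-12

    @given(p=st.floats(1e-6, 0.05), years=st.floats(1.0, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_small_risk_agreement(self, p, years):
        lin = cumulative_to_annual(p, years, "linear")
        expo = cumulative_to_annual(p, years, "exponential")
        assert abs(lin - expo) <= 0.10 * lin


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec(kind="beta", a=8, b=186),
            gamma_from_mean_sd(36_351.0, 4401.0),
            DistributionSpec(kind="normal", a=0.696, b=0.029),
            DistributionSpec(
                kind="beta_sum",
                components=[
                    DistributionSpec(kind="beta", a=266, b=17_284),
                    DistributionSpec(kind="beta", a=1592, b=15_958),
                ],
            ),
            point(0.05),
        ],
        ids=["beta", "gamma", "normal", "beta_sum", "point"],
    )
    def test_analytic_mean_matches_monte_carlo(self, spec):
        """Sample mean of 1e6 draws within 3 Monte-Carlo SEs of the mean."""
        rng = np.random.default_rng(20_240_101)
        n = 1_000_000
        x = spec.draw(rng, size=n)
        se = spec.sd() / math.sqrt(n)
        assert abs(float(np.mean(x)) - spec.mean()) <= 3.0 * se + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec(kind="beta", a=0, b=5)
        with pytest.raises(ValidationError):
            DistributionSpec(kind="normal", a=0.5, b=-0.1)
        with pytest.raises(ValidationError):
            DistributionSpec(kind="point", a=1.0, components=[point(1.0)])

    def test_truncated_draws_stay_in_bounds(self):
        spec = DistributionSpec(kind="normal", a=0.97, b=0.2, truncation=(0.0, 1.0))
        rng = np.random.default_rng(3)
        x = spec.draw(rng, size=20_000)
        assert x.min() >= 0.0 and x.max() <= 1.0
        # truncation shifts the realized mean below the untruncated one
        assert float(np.mean(x)) < 0.97

    def test_rescale_keeps_dispersion_structure(self):
        b = rescale_to_mean(DistributionSpec(kind="beta", a=8, b=186), 0.0086)
        assert b.a + b.b == pytest.approx(194.0)
        assert beta_mean(b) == pytest.approx(0.0086)
        g = rescale_to_mean(gamma_from_mean_sd(1000.0, 100.0), 2000.0)
        assert g.a * g.b == pytest.approx(2000.0)
        assert g.sd() / g.mean() == pytest.approx(0.1)  # CV preserved

    def test_beta_from_mean_n(self):
        spec = beta_from_mean_n(0.002, 9725.0)
        assert beta_mean(spec) == pytest.approx(0.002)
        assert spec.a + spec.b == pytest.approx(9725.0)


class TestUncertainParam:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(base_value=1.2, unit="probability_per_year"),
            dict(base_value=-5.0, unit="usd"),
            dict(base_value=1.5, unit="utility"),
        ],
    )
    def test_unit_ranges_enforced(self, kwargs):
        with pytest.raises(ValidationError):
            UncertainParam(**kwargs)

    def test_default_dist_is_point_at_base(self):
        p = UncertainParam(base_value=0.05, unit="utility")
        assert p.dist.kind == "point" and p.dist.a == 0.05


class TestScenarioIO:
    def test_round_trip_is_identity(self, low_risk, small_tumor):
        for sc in (low_risk, small_tumor):
            assert load_scenario(write_scenario(sc)) == sc

    def test_out_of_range_probability_names_path(self, low_risk):
        data = low_risk.model_dump(mode="json")
        data["bcs"]["p_local_annual"]["base_value"] = 1.2
        with pytest.raises(ValidationError) as err:
            Scenario.model_validate(data)
        assert "p_local_annual" in str(err.value)

    def test_unknown_keys_rejected(self, low_risk):
        data = low_risk.model_dump(mode="json")
        data["unexpected_knob"] = 1
        with pytest.raises(ValidationError) as err:
            Scenario.model_validate(data)
        assert "unexpected_knob" in str(err.value)

    def test_risk_sum_constraint(self, low_risk):
        data = low_risk.model_dump(mode="json")
        for key in ("p_local_annual", "p_distant_annual", "p_mortality_annual"):
            data["bca"][key]["base_value"] = 0.4
        with pytest.raises(ValidationError):
            Scenario.model_validate(data)

    def test_non_mapping_rejected(self):
        with pytest.raises(ValueError):
            load_scenario("- just\n- a list\n")
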