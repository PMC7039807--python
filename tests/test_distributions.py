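"""Distribution fitting and truncated sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from pmburden.distributions import (
    DistributionSpec,
    Family,
    Truncation,
    fit_beta_to_mean_sd,
    fit_lognormal_to_mean_and_percentiles,
    fit_lognormal_to_mean_sd,
    fit_weibull_to_mean_sd,
    point,
    sample,
    scale_spec,
    spec_mean,
    substream_seed,
)

Z10, Z90 = stats.norm.ppf(0.1), stats.norm.ppf(0.9)


def lognormal_summary(gm, gsd):
    mu, sig = np.log(gm), np.log(gsd)
    return (
        np.exp(mu + sig**2 / 2),
        np.exp(mu + sig * Z10),
        np.exp(mu + sig * Z90),
    )


class TestLognormalPercentileFit:
    def test_national_outdoor_summary_matches_published_fit(self):
        # the published parameters (GM 8.84, GSD 1.246) are themselves not
        # exactly quantile-consistent with the inputs, so agreement is at
        # the few-percent level, not to printed precision
        spec = fit_lognormal_to_mean_and_percentiles(9.1, 6.6, 11.2)
        assert spec.params["gm"] == pytest.approx(8.84, rel=0.05)
        assert spec.params["gsd"] == pytest.approx(1.246, rel=0.05)

    def test_exact_lognormal_triple_recovered(self):
        mean, p10, p90 = lognormal_summary(10.0, 1.5)
        spec = fit_lognormal_to_mean_and_percentiles(mean, p10, p90)
        assert spec.params["gm"] == pytest.approx(10.0, rel=1e-6)
        assert spec.params["gsd"] == pytest.approx(1.5, rel=1e-6)

    def test_division_summary_reproduced_within_5pct(self):
        # South Atlantic outdoor summary
        spec = fit_lognormal_to_mean_and_percentiles(8.86, 6.90, 10.66)
        mean, p10, p90 = lognormal_summary(spec.params["gm"], spec.params["gsd"])
        assert mean == pytest.approx(8.86, rel=0.05)
        assert p10 == pytest.approx(6.90, rel=0.05)
        assert p90 == pytest.approx(10.66, rel=0.05)

    @pytest.mark.parametrize("bad", [(9.1, -1.0, 11.2), (5.0, 6.0, 11.2), (9.1, 6.6, 6.0)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_lognormal_to_mean_and_percentiles(*bad)


class TestWeibullFit:
    def test_effect_estimate_fit_near_published_parameters(self):
        spec = fit_weibull_to_mean_sd(0.0070, 0.0016)
        assert spec.params["shape"] == pytest.approx(4.95, rel=0.05)
        assert spec.params["scale"] == pytest.approx(0.00765, rel=0.02)

    def test_mean_identity_exact(self):
        spec = fit_weibull_to_mean_sd(0.0070, 0.0016)
        k, lam = spec.params["shape"], spec.params["scale"]
        assert lam * special.gamma(1 + 1 / k) == pytest.approx(0.0070, rel=1e-9)

    def test_fitted_percentiles_bracket_published_ci(self):
        spec = fit_weibull_to_mean_sd(0.0070, 0.0016)
        d = stats.weibull_min(spec.params["shape"], scale=spec.params["scale"])
        assert d.ppf(0.025) == pytest.approx(0.0036, rel=0.15)
        assert d.ppf(0.975) == pytest.approx(0.0104, rel=0.15)

    def test_sampling_oracle_recovers_moments(self):
        spec = fit_weibull_to_mean_sd(1.0, 0.1)
        draws = sample(spec, 10**6, seed=123)
        assert draws.mean() == pytest.approx(1.0, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(0.1, rel=0.01)

    @pytest.mark.parametrize("sd", [1e-7, 1e7])
    def test_cv_outside_searchable_range_rejected(self, sd):
        with pytest.raises(ValueError):
            fit_weibull_to_mean_sd(1.0, sd)


class TestBetaFit:
    def test_infiltration_summary_closed_form(self):
        # New England residential infiltration factor: mean 0.50, SD 0.08
        spec = fit_beta_to_mean_sd(0.50, 0.08, 0.0, 1.0)
        a, b = spec.params["a"], spec.params["b"]
        assert a / (a + b) == pytest.approx(0.50, rel=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(0.08**2, rel=1e-12)

    def test_zero_sd_collapses_to_point(self):
        spec = fit_beta_to_mean_sd(0.5, 0.0, 0.0, 1.0)
        assert spec.family is Family.POINT
        assert spec.params["value"] == 0.5

    def test_moments_of_fitted_shapes(self):
        spec = fit_beta_to_mean_sd(0.40, 0.08, 0.0, 1.0)
        a, b = spec.params["a"], spec.params["b"]
        assert a / (a + b) == pytest.approx(0.40)
        assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(0.0064)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_to_mean_sd(0.5, 0.6, 0.0, 1.0)


class TestRoundTrips:
    @given(
        gm=st.floats(0.5, 50.0),
        gsd=st.floats(1.05, 3.0),
    )
    def test_lognormal_percentile_round_trip(self, gm, gsd):
        spec = fit_lognormal_to_mean_and_percentiles(*lognormal_summary(gm, gsd))
        assert spec.params["gm"] == pytest.approx(gm, rel=1e-6)
        assert spec.params["gsd"] == pytest.approx(gsd, rel=1e-6)

    @given(mean=st.floats(0.1, 100.0), cv=st.floats(0.05, 0.9))
    def test_lognormal_moment_round_trip(self, mean, cv):
        spec = fit_lognormal_to_mean_sd(mean, cv * mean)
        gm, gsd = spec.params["gm"], spec.params["gsd"]
        implied_mean = gm * np.exp(np.log(gsd) ** 2 / 2)
        implied_var = implied_mean**2 * (np.exp(np.log(gsd) ** 2) - 1)
        assert implied_mean == pytest.approx(mean, rel=1e-9)
        assert np.sqrt(implied_var) == pytest.approx(cv * mean, rel=1e-9)

    @given(mean=st.floats(0.01, 10.0), cv=st.floats(0.05, 0.8))
    def test_weibull_round_trip(self, mean, cv):
        spec = fit_weibull_to_mean_sd(mean, cv * mean)
        d = stats.weibull_min(spec.params["shape"], scale=spec.params["scale"])
        assert d.mean() == pytest.approx(mean, rel=1e-6)
        assert d.std() == pytest.approx(cv * mean, rel=1e-6)

    @given(
        mean=st.floats(0.05, 0.95),
        sd=st.floats(0.01, 0.15),
    )
    def test_beta_round_trip(self, mean, sd):
        if sd**2 >= mean * (1 - mean) * 0.99:
            return
        spec = fit_beta_to_mean_sd(mean, sd, 0.0, 1.0)
        a, b = spec.params["a"], spec.params["b"]
        assert a / (a + b) == pytest.approx(mean, rel=1e-6)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(sd, rel=1e-6)


class TestSampling:
    def test_point_spec_repeats_value(self):
        assert np.array_equal(sample(point(9.1), 3, seed=0), [9.1, 9.1, 9.1])

    def test_truncated_standard_normal_is_half_normal(self):
        spec = DistributionSpec(
            Family.NORMAL, {"mean": 0.0, "sd": 1.0},
            truncation=Truncation.REPLACE_NEGATIVE_WITH_ZERO,
        )
        draws = sample(spec, 200_000, seed=5)
        assert np.all(draws >= 0)
        assert np.mean(draws == 0.0) == pytest.approx(0.5, abs=0.01)
        # E[max(X, 0)] = 1/sqrt(2*pi)
        assert draws.mean() == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.01)

    def test_lognormal_sample_mean_matches_closed_form(self):
        spec = DistributionSpec(Family.LOGNORMAL, {"gm": 8.84, "gsd": 1.246})
        draws = sample(spec, 10**5, seed=11)
        expected = 8.84 * np.exp(np.log(1.246) ** 2 / 2)
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_determinism_under_fixed_seed(self):
        spec = fit_weibull_to_mean_sd(0.007, 0.0016)
        a = sample(spec, 1000, seed=substream_seed(42, "beta"))
        b = sample(spec, 1000, seed=substream_seed(42, "beta"))
        c = sample(spec, 1000, seed=substream_seed(43, "beta"))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_substreams_are_independent_by_key(self):
        spec = DistributionSpec(Family.NORMAL, {"mean": 0.0, "sd": 1.0})
        a = sample(spec, 1000, seed=substream_seed(1, "x"))
        b = sample(spec, 1000, seed=substream_seed(1, "y"))
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample(point(1.0), 0, seed=0)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "family,params",
        [
            (Family.LOGNORMAL, {"gm": 1.0, "gsd": 0.9}),
            (Family.WEIBULL, {"shape": -1.0, "scale": 1.0}),
            (Family.BETA, {"a": 0.0, "b": 2.0}),
            (Family.BETA, {"a": 1.0, "b": 1.0, "lower": 1.0, "upper": 0.0}),
            (Family.LOGNORMAL, {"gm": 1.0}),
        ],
    )
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValueError):
            DistributionSpec(family, params)

    def test_serialization_round_trip(self):
        spec = fit_beta_to_mean_sd(0.5, 0.08, units="dimensionless")
        assert DistributionSpec.from_dict(spec.to_dict()) == spec

    def test_unknown_serialized_key_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec.from_dict(
                {"family": "point", "params": {"value": 1}, "bogus": 2}
            )


class TestScaleSpec:
    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec(Family.LOGNORMAL, {"gm": 8.84, "gsd": 1.246}),
            fit_weibull_to_mean_sd(0.007, 0.0016),
            fit_beta_to_mean_sd(0.5, 0.08),
            DistributionSpec(Family.NORMAL, {"mean": 2.0, "sd": 0.5}),
            point(3.0),
        ],
    )
    def test_scaling_multiplies_draws(self, spec):
        scaled = scale_spec(spec, 1.0 / 0.6)
        a = sample(spec, 500, seed=substream_seed(9, "s")) / 0.6
        b = sample(scaled, 500, seed=substream_seed(9, "s"))
        np.testing.assert_allclose(a, b, rtol=1e-12)
        assert spec_mean(scaled) == pytest.approx(spec_mean(spec) / 0.6, rel=1e-12)
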