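"""Parametric survival fitting, model comparison and schedule construction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from asuc_cua import (
    compare_fits,
    fit_parametric,
    fixed_tp_schedule,
    km_estimate,
    logrank_test,
    probability_from_rate,
    rate_from_probability,
    tp_schedule_from_weibull,
    weibull_tp_schedule,
)
from asuc_cua.errors import FitError, ValidationError


def make_records(times, events, **covariates):
    df = pd.DataFrame({"observed_time_years": times, "event": events})
    for name, vals in covariates.items():
        df[name] = vals
    return df


def weibull_records(n, shape, scale, censor=2.0, seed=0):
    rng = np.random.default_rng(seed)
    latent = (-np.log(rng.uniform(size=n)) / scale) ** (1.0 / shape)
    return make_records(np.minimum(latent, censor), (latent <= censor).astype(int))


class TestFitting:
    def test_exponential_closed_form_mle(self):
        rec = make_records([0.5, 1.2, 2.0, 2.0, 0.8], [1, 1, 0, 0, 1])
        fit = fit_parametric(rec, "exponential")
        assert fit.scale == pytest.approx(3 / rec.observed_time_years.sum(), abs=0)
        assert fit.shape == 1.0

    @pytest.mark.parametrize("family", ["weibull", "exponential", "gompertz", "loglogistic"])
    def test_loglikelihood_matches_independent_evaluation(self, family):
        """Reported log-likelihood equals a from-scratch evaluation of
        sum(d * log h) + sum(log S) at the returned parameters, with the
        cumulative hazard obtained by numerical integration of the hazard."""
        rec = weibull_records(300, 0.7, 0.3, seed=4)
        fit = fit_parametric(rec, family)
        g, lam = fit.shape, fit.scale

        def hazard(t):
            if family == "weibull":
                return lam * g * t ** (g - 1.0)
            if family == "exponential":
                return lam
            if family == "gompertz":
                return lam * math.exp(g * t)
            a = lam  # log-logistic: lam is the location scale alpha
            z = (t / a) ** g
            return (g / a) * (t / a) ** (g - 1.0) / (1.0 + z)

        ll = 0.0
        for t, d in zip(rec.observed_time_years, rec.event):
            H = quad(hazard, 0.0, t, points=[t / 2], limit=200)[0]
            ll += d * math.log(hazard(t)) - H
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_weibull_matches_lifelines(self):
        """Cross-check against lifelines' AFT parameterisation:
        S(t) = exp(-(t/lambda_)**rho_), so shape = rho_ and
        scale = lambda_**(-rho_)."""
        from lifelines import WeibullFitter

        rec = weibull_records(2000, 0.6, 0.25, seed=9)
        fit = fit_parametric(rec, "weibull")
        wf = WeibullFitter().fit(rec.observed_time_years, rec.event)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-4)
        assert fit.scale == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-4)

    def test_covariate_hazard_ratio_matches_lifelines(self):
        """PH log-HR equals -rho * (AFT coefficient) for the Weibull model."""
        from lifelines import WeibullAFTFitter

        rng = np.random.default_rng(12)
        n = 4000
        x = rng.normal(0.0, 1.0, n)
        latent = (-np.log(rng.uniform(size=n)) / (0.3 * np.exp(0.4 * x))) ** (1 / 0.7)
        rec = make_records(np.minimum(latent, 2.0), (latent <= 2.0).astype(int), x=x)
        fit = fit_parametric(rec, "weibull", covariate_names=("x",))
        aft = WeibullAFTFitter().fit(rec, duration_col="observed_time_years", event_col="event")
        rho = float(aft.params_[("rho_", "Intercept")])
        beta_aft = float(aft.params_[("lambda_", "x")])
        assert fit.coefficients["x"] == pytest.approx(-math.exp(rho) * beta_aft, rel=1e-3)

    def test_no_events_is_a_fit_error(self):
        rec = make_records([1.0, 2.0], [0, 0])
        with pytest.raises(FitError):
            fit_parametric(rec, "weibull")

    def test_aic_bic_relationship(self):
        rec = weibull_records(200, 0.8, 0.3, seed=2)
        fit = fit_parametric(rec, "weibull")
        k = fit.n_params
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(k * math.log(fit.n) - 2 * fit.log_likelihood)


class TestCompareFits:
    def test_single_fit_ranked_first(self):
        rec = weibull_records(100, 1.0, 0.3, seed=1)
        fit = fit_parametric(rec, "exponential")
        table = compare_fits([fit])
        assert table.loc[0, "rank_aic"] == 1

    def test_nesting_penalty_bound(self):
        """On exponential data, AIC(exponential) <= AIC(weibull) + 2 always
        (weibull nests the exponential with one extra parameter)."""
        for seed in range(5):
            rec = weibull_records(150, 1.0, 0.4, seed=seed)
            fe = fit_parametric(rec, "exponential")
            fw = fit_parametric(rec, "weibull")
            assert fe.aic <= fw.aic + 2 + 1e-6

    def test_weibull_beats_exponential_when_shape_far_from_one(self):
        rec = weibull_records(3000, 0.4, 0.3, seed=5)
        fits = [fit_parametric(rec, f) for f in ("weibull", "exponential")]
        table = compare_fits(fits)
        assert table.loc[0, "family"] == "weibull"

    def test_differing_data_rejected(self):
        a = fit_parametric(weibull_records(100, 1.0, 0.3, seed=1), "exponential")
        b = fit_parametric(weibull_records(120, 1.0, 0.3, seed=1), "exponential")
        with pytest.raises(ValidationError, match="identical data"):
            compare_fits([a, b])


class TestTPSchedule:
    def test_exponential_limit_constant(self):
        s = weibull_tp_schedule(1.0, 0.2, 10)
        np.testing.assert_allclose(s.probabilities, 1 - math.exp(-0.2), rtol=1e-12)

    def test_first_cycles_from_survival_ratio(self):
        """tp(t) = 1 - S(t)/S(t-1) at the published point estimates."""
        s = weibull_tp_schedule(0.393, 0.111, 18)
        S = lambda t: math.exp(-0.111 * t**0.393)
        assert s.tp(1) == pytest.approx(1 - S(1), abs=1e-12)
        assert s.tp(2) == pytest.approx(1 - S(2) / S(1), abs=1e-12)
        assert s.tp(1) == pytest.approx(0.10506, abs=5e-6)
        assert s.tp(2) == pytest.approx(0.03416, abs=5e-6)

    def test_strictly_decreasing_when_shape_below_one(self):
        s = weibull_tp_schedule(0.45, 0.186, 18)
        assert np.all(np.diff(s.probabilities) < 0)

    def test_schedule_conserves_cumulative_probability(self):
        """prod(1-tp) telescopes to S(H) exactly."""
        for shape, scale in [(0.393, 0.111), (0.45, 0.186), (1.3, 0.05)]:
            s = weibull_tp_schedule(shape, scale, 18)
            expected = 1 - math.exp(-scale * 18**shape)
            assert s.cumulative_event_probability() == pytest.approx(expected, abs=1e-10)

    def test_profile_shifts_schedule_by_hazard_ratio(self):
        rec = weibull_records(500, 0.5, 0.3, seed=6)
        rec["age"] = np.random.default_rng(0).normal(40, 10, len(rec))
        fit = fit_parametric(rec, "weibull", covariate_names=("age",))
        base = tp_schedule_from_weibull(fit, horizon_cycles=5)
        older = tp_schedule_from_weibull(
            fit, {"age": fit.covariate_center["age"] + 10}, horizon_cycles=5
        )
        hr = math.exp(10 * fit.coefficients["age"])
        surv_base = 1 - base.probabilities[0]
        assert 1 - older.probabilities[0] == pytest.approx(surv_base**hr, rel=1e-10)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValidationError):
            weibull_tp_schedule(0.5, 0.1, 0)
        with pytest.raises(ValidationError):
            fixed_tp_schedule(1.5, 10)


class TestRateConversions:
    def test_zero_probability(self):
        assert rate_from_probability(0.0, 3.0) == 0.0
        assert probability_from_rate(0.0, 1.0) == 0.0

    def test_three_year_mortality_example(self):
        r = rate_from_probability(0.2, 3.0)
        assert r == pytest.approx(-math.log(0.8) / 3.0, abs=1e-15)
        assert r == pytest.approx(0.074381, abs=1e-6)
        assert probability_from_rate(r, 1.0) == pytest.approx(0.071682, abs=1e-6)

    def test_round_trip_identity(self):
        for p in (0.0, 1e-6, 0.2, 0.9, 0.999):
            r = rate_from_probability(p, 1.0)
            assert probability_from_rate(r, 1.0) == pytest.approx(p, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError, match="infinite"):
            rate_from_probability(1.0, 1.0)
        with pytest.raises(ValidationError):
            rate_from_probability(-0.1, 1.0)
        with pytest.raises(ValidationError):
            rate_from_probability(0.5, 0.0)


class TestNonParametric:
    def test_km_equals_empirical_survival_without_censoring(self):
        rec = make_records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        km = km_estimate(rec)
        surv_at = dict(zip(km.time, km.survival))
        assert surv_at[2.0] == pytest.approx(0.5)
        assert surv_at[4.0] == pytest.approx(0.0)

    def test_identical_arms_give_null_logrank(self):
        rec = make_records([0.5, 1.0, 1.5, 2.0] * 2, [1, 1, 0, 1] * 2)
        rec["arm"] = ["a"] * 4 + ["b"] * 4
        stat, p = logrank_test(rec)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_single_arm_rejected(self):
        rec = make_records([1.0, 2.0], [1, 0])
        rec["arm"] = "only"
        with pytest.raises(ValidationError, match="2 arms"):
            logrank_test(rec)

    def test_logrank_p_close_to_permutation_null(self):
        """The chi-square p-value agrees with a label-permutation estimate."""
        rng = np.random.default_rng(21)
        n = 40
        t_a = np.minimum((-np.log(rng.uniform(size=n)) / 0.5), 2.0)
        t_b = np.minimum((-np.log(rng.uniform(size=n)) / 0.9), 2.0)
        times = np.concatenate([t_a, t_b])
        events = (times < 2.0).astype(int)
        rec = make_records(times, events)
        rec["arm"] = ["a"] * n + ["b"] * n
        stat, p = logrank_test(rec)
        n_perm, exceed = 400, 0
        for _ in range(n_perm):
            shuffled = rec.copy()
            shuffled["arm"] = rng.permutation(rec["arm"].to_numpy())
            s, _ = logrank_test(shuffled)
            exceed += s >= stat
        p_perm = exceed / n_perm
        assert abs(p - p_perm) < 3 * math.sqrt(max(p_perm * (1 - p_perm), 0.01) / n_perm) + 0.02
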