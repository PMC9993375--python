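"""Scenario engine, PSA distributions, CEAC construction."""

import math
from dataclasses import replace

import numpy as np
import pytest

from asuc_cua import beta_from_moments, ceac, gamma_from_moments, run_psa, run_scenario
from asuc_cua.errors import ValidationError
from asuc_cua.pipeline import run_base_case
from asuc_cua.sensitivity import (
    PSAResult,
    ScenarioSpec,
    default_scenarios,
    probability_cost_effective,
    run_scenarios,
)


class TestMomentMatching:
    def test_beta_closed_form(self):
        assert beta_from_moments(0.8, 0.1) == pytest.approx((12.0, 3.0))

    def test_beta_concentrates_as_se_vanishes(self):
        a, b = beta_from_moments(0.5, 1e-6)
        assert a == pytest.approx(b)
        assert a > 1e10

    def test_beta_infeasible_variance(self):
        with pytest.raises(ValidationError, match="reduce the SE"):
            beta_from_moments(0.5, 0.6)
        with pytest.raises(ValidationError):
            beta_from_moments(1.2, 0.1)

    def test_beta_simulated_moments(self):
        a, b = beta_from_moments(0.8, 0.1)
        draws = np.random.default_rng(0).beta(a, b, 1_000_000)
        assert abs(draws.mean() - 0.8) < 4 * 0.1 / math.sqrt(1_000_000)
        assert draws.std() == pytest.approx(0.1, abs=2e-3)

    def test_gamma_closed_form(self):
        shape, scale = gamma_from_moments(1000.0, 200.0)
        assert (shape, scale) == pytest.approx((25.0, 40.0))
        assert shape * scale == 1000.0
        assert shape * scale**2 == 200.0**2

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            gamma_from_moments(-1.0, 2.0)
        with pytest.raises(ValidationError):
            gamma_from_moments(1.0, 0.0)


class TestScenarioEngine:
    def test_identity_scenario_equals_base_case(self, base_inputs):
        base = run_base_case(base_inputs)
        identity = run_scenario(base_inputs, ScenarioSpec("identity"))
        assert identity.comparison == base.comparison
        assert identity.reference.combined == base.reference.combined

    def test_price_scenarios_leave_qalys_unchanged_and_scale_linearly(self, base_inputs):
        base = run_base_case(base_inputs)
        r10 = run_scenario(base_inputs, ScenarioSpec("p10", infliximab_price_multiplier=0.9))
        r50 = run_scenario(base_inputs, ScenarioSpec("p50", infliximab_price_multiplier=0.5))
        for r in (r10, r50):
            assert r.reference.combined.qaly == pytest.approx(base.reference.combined.qaly)
            assert r.comparator.combined == base.comparator.combined
        red10 = base.reference.combined.cost - r10.reference.combined.cost
        red50 = base.reference.combined.cost - r50.reference.combined.cost
        assert red50 == pytest.approx(5.0 * red10, rel=1e-9)

    def test_utility_scenario_leaves_all_costs_unchanged(self, base_inputs):
        base = run_base_case(base_inputs)
        res = run_scenario(
            base_inputs, ScenarioSpec("u", utility_multiplier={"ciclosporin": 0.9})
        )
        assert res.reference.combined == base.reference.combined
        assert res.comparator.combined.cost == pytest.approx(base.comparator.combined.cost)
        assert res.comparator.combined.qaly < base.comparator.combined.qaly

    def test_fixed_tp_scenario_changes_costs_and_qalys(self, base_inputs):
        base = run_base_case(base_inputs)
        res = run_scenario(base_inputs, ScenarioSpec("tp", tp_mode="fixed"))
        assert res.reference.combined.cost != base.reference.combined.cost
        assert res.reference.combined.qaly != base.reference.combined.qaly

    def test_shorter_horizon_reduces_totals(self, base_inputs):
        base = run_base_case(base_inputs)
        res = run_scenario(base_inputs, ScenarioSpec("h10", horizon_years=10))
        assert res.reference.combined.qaly < base.reference.combined.qaly
        assert res.reference.combined.cost < base.reference.combined.cost

    def test_twelve_default_scenarios(self, base_inputs):
        scenarios = default_scenarios()
        assert len(scenarios) == 12
        table = run_scenarios(base_inputs, scenarios)
        assert len(table) == 13  # base case + 12
        assert (table.cost_effectiveness.str.contains("dominates|ICER")).all()

    def test_unknown_tp_mode_rejected(self, base_inputs):
        with pytest.raises(ValidationError, match="tp_mode"):
            run_scenario(base_inputs, ScenarioSpec("bad", tp_mode="spline"))


class TestPSA:
    def test_zero_ses_degenerate_to_base_case(self, base_inputs, config):
        psa = replace(
            config.psa,
            n_draws=5,
            utility_se=0.0,
            cost_se_fraction=0.0,
            mortality_se=0.0,
            weibull={
                arm: replace(w, shape_se=0.0, scale_se=0.0)
                for arm, w in config.psa.weibull.items()
            },
        )
        base = run_base_case(base_inputs)
        res = run_psa(base_inputs, psa)
        np.testing.assert_allclose(res.delta_cost, base.comparison.delta_cost, rtol=1e-12)
        np.testing.assert_allclose(res.delta_qaly, base.comparison.delta_qaly, rtol=1e-12)

    def test_reproducible_given_seed(self, base_inputs, config):
        psa = replace(config.psa, n_draws=10, seed=123)
        a = run_psa(base_inputs, psa)
        b = run_psa(base_inputs, psa)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        c = run_psa(base_inputs, replace(psa, seed=124))
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_mean_draws_near_deterministic_base(self, base_inputs, config):
        """For this near-linear model the PSA mean tracks the base case."""
        psa = replace(config.psa, n_draws=400, seed=7)
        base = run_base_case(base_inputs)
        res = run_psa(base_inputs, psa)
        for draws, det in (
            (res.delta_cost, base.comparison.delta_cost),
            (res.delta_qaly, base.comparison.delta_qaly),
        ):
            se = draws.std(ddof=1) / math.sqrt(len(draws))
            assert abs(draws.mean() - det) < 4 * se

    def test_infeasible_parameterisation_fails_before_any_draw(self, base_inputs, config):
        bad = replace(
            config.psa,
            weibull={arm: replace(w, scale_se=0.9) for arm, w in config.psa.weibull.items()},
        )
        with pytest.raises(ValidationError, match="weibull"):
            run_psa(base_inputs, bad)


class TestCEAC:
    @staticmethod
    def synthetic_result(dc, de):
        return PSAResult(
            delta_cost=np.asarray(dc, dtype=float),
            delta_qaly=np.asarray(de, dtype=float),
            seed=0,
            n_draws=len(dc),
        )

    def test_all_dominant_draws_give_unity(self):
        res = self.synthetic_result([-100.0] * 50, [0.1] * 50)
        curve = ceac(res, [0.0, 10_000.0, 50_000.0])
        assert (curve.probability_cost_effective == 1.0).all()

    def test_constructed_95_percent_case(self):
        """9,500 dominant draws and 500 dominated ones: the acceptability is
        0.95 across the whole threshold grid, including 20,000/QALY."""
        n_good, n_bad = 9_500, 500
        res = self.synthetic_result(
            [-1000.0] * n_good + [1000.0] * n_bad,
            [0.5] * n_good + [-0.5] * n_bad,
        )
        grid = np.arange(0.0, 50_001.0, 500.0)
        curve = ceac(res, grid)
        assert (curve.probability_cost_effective == 0.95).all()
        assert probability_cost_effective(res, 20_000.0) == 0.95

    def test_value_at_zero_wtp_is_fraction_cost_saving(self):
        res = self.synthetic_result([-10.0, -5.0, 5.0, 10.0], [0.1, -0.1, 0.1, -0.1])
        curve = ceac(res, [0.0])
        assert curve.probability_cost_effective.iloc[0] == 0.5

    def test_monotone_for_ne_and_dominant_draws(self):
        rng = np.random.default_rng(0)
        res = self.synthetic_result(rng.uniform(-100, 500, 200), rng.uniform(0.01, 0.5, 200))
        curve = ceac(res, np.arange(0.0, 30_001.0, 1000.0))
        assert (np.diff(curve.probability_cost_effective) >= 0).all()

    def test_sw_quadrant_draws_give_decreasing_curve(self):
        """Cheaper-but-less-effective draws are cost-effective only at low
        thresholds, so the curve may decrease."""
        res = self.synthetic_result([-1000.0] * 10, [-0.1] * 10)
        curve = ceac(res, [0.0, 5_000.0, 20_000.0])
        probs = curve.probability_cost_effective.to_numpy()
        assert probs[0] == 1.0 and probs[-1] == 0.0
        assert (np.diff(probs) <= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError, match="grid"):
            ceac(self.synthetic_result([1.0], [1.0]), [])

    def test_tie_counts_as_not_cost_effective(self):
        res = self.synthetic_result([100.0], [0.01])  # ICER exactly 10,000
        assert probability_cost_effective(res, 10_000.0) == 0.0
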