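"""One-way scenario analysis and probabilistic sensitivity analysis."""
import dataclasses

import numpy as np
import pytest

from wmcea.cea import run_base_case
from wmcea.params import calibrated_to_dict
from wmcea.sensitivity import (
    CEACPoint,
    DSAScenario,
    PSASpec,
    ScenarioError,
    apply_scenario,
    ceac,
    hr_log_sd_from_ci,
    run_dsa,
    run_psa,
    run_scenario,
    sample_psa,
    table_scenarios,
)


class TestScenarios:
    def test_applying_a_scenario_leaves_the_base_untouched(self, params):
        snapshot = calibrated_to_dict(params)
        run_dsa(params, table_scenarios()[:3])
        assert calibrated_to_dict(params) == snapshot

    def test_scenario_equal_to_base_changes_nothing(self, params):
        noop = DSAScenario("noop", "base values", settings={"horizon_years": 15.0})
        base = run_base_case(params)
        res = run_scenario(params, noop)
        assert res.icer == pytest.approx(base.icer, rel=1e-14)

    def test_unknown_parameter_path_raises(self, params):
        bad = DSAScenario("bad", "typo", settings={"horizon_yrs": 10})
        with pytest.raises(ScenarioError):
            apply_scenario(params, bad)

    def test_zero_effect_discount_raises_ly_not_costs(self, params):
        base = run_base_case(params)
        res = run_scenario(
            params, DSAScenario("e0", "", settings={"discount_rate_effects": 0.0})
        )
        assert res.arm_a.costs.total == pytest.approx(base.arm_a.costs.total, rel=1e-12)
        assert res.arm_a.life_years.discounted_ly > base.arm_a.life_years.discounted_ly
        assert res.icer < base.icer

    def test_no_subsequent_lines_cuts_costs_not_survival(self, params):
        base = run_base_case(params)
        res = run_scenario(
            params, DSAScenario("s0", "", subsequent_lines_active=False)
        )
        assert res.delta_ly == pytest.approx(base.delta_ly, abs=1e-12)
        assert res.arm_a.costs.total < base.arm_a.costs.total
        assert res.arm_b.costs.total < base.arm_b.costs.total

    def test_price_scenario_shifts_only_the_ibrutinib_drug_component(self, params):
        base = run_base_case(params)
        res = run_scenario(
            params, DSAScenario("p", "", ibrutinib_price_multiplier=1.2)
        )
        assert res.arm_a.costs.drug == pytest.approx(1.2 * base.arm_a.costs.drug)
        assert res.arm_a.costs.sae == pytest.approx(base.arm_a.costs.sae)
        assert res.arm_b.costs.total == pytest.approx(base.arm_b.costs.total)

    def test_better_post_progression_efficacy_adds_life_years(self, params):
        base = run_base_case(params)
        better = run_scenario(
            params, DSAScenario("pp", "", dwell_hazard_multiplier=1 / 1.2)
        )
        worse = run_scenario(
            params, DSAScenario("pm", "", dwell_hazard_multiplier=1 / 0.8)
        )
        for arm_new, arm_base in (
            (better.arm_a, base.arm_a), (better.arm_b, base.arm_b),
        ):
            assert arm_new.life_years.discounted_ly > arm_base.life_years.discounted_ly
        assert worse.arm_a.life_years.discounted_ly < base.arm_a.life_years.discounted_ly

    def test_percent_change_column_matches_icer_ratio(self, params):
        table = run_dsa(params, table_scenarios())
        base_icer = table.loc[table.scenario == "base_case", "icer"].item()
        for _, row in table.iterrows():
            expected = (row.icer / base_icer - 1.0) * 100.0
            assert row.pct_vs_base == pytest.approx(expected, abs=0.1)


class TestPSA:
    def test_degenerate_distributions_reproduce_the_base(self, params):
        spec = PSASpec(n_samples=3, seed=5, hr_log_sd=0.0, cost_cv=0.0,
                       rate_cv=0.0, survival_log_sd=0.0)
        for draw in sample_psa(params, spec):
            assert draw.hr.point == params.hr.point
            assert draw.pfs_ibrutinib == params.pfs_ibrutinib
            assert draw.sae_rates == params.sae_rates
            assert draw.monitoring_costs == params.monitoring_costs

    def test_single_degenerate_draw_equals_base_case(self, params):
        spec = PSASpec(n_samples=1, seed=5, hr_log_sd=0.0, cost_cv=0.0,
                       rate_cv=0.0, survival_log_sd=0.0)
        pairs = run_psa(params, spec)
        base = run_base_case(params)
        assert pairs[0, 0] == pytest.approx(base.delta_cost, rel=1e-12)
        assert pairs[0, 1] == pytest.approx(base.delta_ly, rel=1e-12)

    def test_same_seed_is_bit_identical(self, params):
        spec = PSASpec(n_samples=40, seed=11)
        assert np.array_equal(run_psa(params, spec), run_psa(params, spec))

    def test_different_seeds_differ(self, params):
        a = run_psa(params, PSASpec(n_samples=10, seed=1))
        b = run_psa(params, PSASpec(n_samples=10, seed=2))
        assert not np.array_equal(a, b)

    def test_hr_log_sd_matches_the_printed_interval(self, params):
        sd = hr_log_sd_from_ci(params.hr)
        z = 1.959963984540054
        assert np.exp(np.log(0.25) - z * sd) == pytest.approx(0.1099, abs=5e-3)
        assert np.exp(np.log(0.25) + z * sd) == pytest.approx(0.5686, abs=5e-3)

    def test_mean_sampled_icer_is_near_the_base_icer(self, params):
        # Monte-Carlo consistency: symmetric-ish sampling around base values
        base = run_base_case(params).icer
        pairs = run_psa(params, PSASpec(n_samples=2000, seed=3))
        icers = pairs[:, 0] / pairs[:, 1]
        assert np.mean(icers) == pytest.approx(base, rel=0.10)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PSASpec(n_samples=0)
        with pytest.raises(ValueError):
            PSASpec(cost_cv=-0.1)


class TestCEAC:
    pairs = np.array([[100.0, 2.0], [200.0, 1.0], [50.0, 4.0]])

    def test_all_positive_nmb_gives_probability_one(self):
        points = ceac(self.pairs, [1000.0])
        assert points == [CEACPoint(1000.0, 1.0)]

    def test_zero_threshold_with_positive_costs_gives_zero(self):
        assert ceac(self.pairs, [0.0])[0].probability_cost_effective == 0.0

    def test_monotone_when_all_draws_gain_life_years(self, params):
        pairs = run_psa(params, PSASpec(n_samples=300, seed=9))
        gainers = pairs[pairs[:, 1] > 0]
        lams = np.linspace(0, 200_000, 41)
        probs = [p.probability_cost_effective for p in ceac(gainers, lams)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_limit_at_large_threshold_is_fraction_gaining_ly(self):
        pairs = np.array([[100.0, 0.5], [100.0, -0.5], [100.0, 1.0], [100.0, 2.0]])
        p = ceac(pairs, [1e12])[0].probability_cost_effective
        assert p == pytest.approx(0.75)

    def test_empty_thresholds_give_empty_list(self):
        assert ceac(self.pairs, []) == []

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)), [1000.0])
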