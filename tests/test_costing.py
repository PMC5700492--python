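"""Activity-based costing: unit arithmetic, state costs, accumulation."""
import dataclasses

import numpy as np
import pytest

from wmcea.costing import (
    CostBreakdown,
    CostingError,
    accumulate_costs,
    administration_cost_per_cycle,
    drug_cost_per_cycle,
    sae_cost_per_cycle,
    state_cycle_cost,
)
from wmcea.engine import HealthState, run_arm_trace
from wmcea.params import (
    ARM_CTP,
    ARM_IBRUTINIB,
    DrugPrice,
    DrugPriceTable,
    Regimen,
    RegimenComponent,
)


def test_ibrutinib_cycle_cost_is_three_capsules_a_day(params):
    # 420 mg/day = 3 x 140 mg capsules, 28 days per cycle at 67.40 EUR
    reg = params.regimen("ibrutinib")
    got = drug_cost_per_cycle(reg, params.prices, params.patient)
    assert got == pytest.approx(3 * 28 * 67.40, abs=1e-9)  # 5,661.60


def test_iv_dose_rounded_up_to_whole_vials(params):
    # rituximab 375 mg/m2 x 1.8 m2 = 675 mg -> 7 x 100 mg vials
    reg = Regimen(
        regimen_id="R",
        components=(RegimenComponent("rituximab", "mg_per_m2", 375, 1, True),),
        iv_days_per_cycle=1,
    )
    got = drug_cost_per_cycle(reg, params.prices, params.patient)
    assert got == pytest.approx(7 * 277.60, abs=1e-9)  # 1,943.20


def test_empty_regimen_costs_nothing(params):
    reg = Regimen(regimen_id="none", components=(), iv_days_per_cycle=0)
    assert drug_cost_per_cycle(reg, params.prices, params.patient) == 0.0
    assert administration_cost_per_cycle(reg, params.tariffs) == 0.0


def test_unpriced_drug_raises_naming_the_drug(params):
    reg = Regimen(
        regimen_id="X",
        components=(RegimenComponent("obinutuzumab", "flat_mg", 1000, 1, True),),
    )
    with pytest.raises(CostingError, match="obinutuzumab"):
        drug_cost_per_cycle(reg, params.prices, params.patient)


def test_administration_tariff_per_iv_day(params):
    oral = params.regimen("ibrutinib")
    assert administration_cost_per_cycle(oral, params.tariffs) == 0.0
    two_days = Regimen(
        regimen_id="BR",
        components=(RegimenComponent("bendamustine", "mg_per_m2", 90, 2, True),),
        iv_days_per_cycle=2,
    )
    assert administration_cost_per_cycle(two_days, params.tariffs) == pytest.approx(
        742.0
    )


class TestSAECosts:
    def test_zero_rates_cost_nothing(self, params):
        assert sae_cost_per_cycle("ctp", {"ctp": {}}, params.tariffs) == 0.0

    def test_incidence_times_tariff(self, params):
        rates = {"ibrutinib": {"neutropenia": 0.01}}
        got = sae_cost_per_cycle("ibrutinib", rates, params.tariffs)
        assert got == pytest.approx(17.04, abs=1e-9)

    def test_two_event_arithmetic(self, params):
        rates = {"ctp": {"anaemia": 0.005, "thrombocytopenia": 0.005}}
        got = sae_cost_per_cycle("ctp", rates, params.tariffs)
        assert got == pytest.approx(0.005 * 1676 + 0.005 * 2748, abs=1e-9)  # 22.12

    def test_untariffed_event_raises(self, params):
        with pytest.raises(CostingError, match="alopecia"):
            sae_cost_per_cycle("ctp", {"ctp": {"alopecia": 0.01}}, params.tariffs)


class TestStateCycleCosts:
    def test_death_costs_nothing(self, params):
        for arm in (ARM_IBRUTINIB, ARM_CTP):
            assert state_cycle_cost(params, arm, HealthState.DEATH, 0) == 0.0

    def test_ctp_initial_cost_is_mix_weighted(self, params):
        # hand-built weighted sum over the pre-progression mix at cycle 0
        expected = 0.0
        for rid, share in params.mix.pre_shares.items():
            reg = params.regimen(rid)
            expected += share * (
                drug_cost_per_cycle(reg, params.prices, params.patient)
                * params.cost_scales.ctp_drug
                + administration_cost_per_cycle(reg, params.tariffs)
                * params.cost_scales.ctp_admin
            )
        expected += sae_cost_per_cycle(ARM_CTP, params.sae_rates, params.tariffs)
        expected += params.monitoring_costs.pre_progression_ctp
        got = state_cycle_cost(params, ARM_CTP, HealthState.INITIAL_TREATMENT, 0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_ctp_treatment_course_ends_after_six_cycles(self, params):
        on = state_cycle_cost(params, ARM_CTP, HealthState.INITIAL_TREATMENT, 5)
        off = state_cycle_cost(params, ARM_CTP, HealthState.INITIAL_TREATMENT, 6)
        assert on > 0
        assert off == 0.0
        # continuous ibrutinib keeps accruing
        late = state_cycle_cost(params, ARM_IBRUTINIB, HealthState.INITIAL_TREATMENT, 100)
        assert late > 0

    def test_subsequent_lines_toggle_keeps_monitoring_only(self, params):
        ps = dataclasses.replace(
            params,
            monitoring_costs=dataclasses.replace(
                params.monitoring_costs, subsequent=42.0
            ),
        )
        with_lines = state_cycle_cost(ps, ARM_CTP, HealthState.SUBSEQUENT_1, 0)
        without = state_cycle_cost(
            ps, ARM_CTP, HealthState.SUBSEQUENT_1, 0, subsequent_lines_active=False
        )
        assert with_lines > without
        assert without == pytest.approx(42.0)


class TestAccumulation:
    def test_zero_cost_parameters_give_zero_breakdown(self, params):
        zero = dataclasses.replace(
            params,
            sae_rates={a: {} for a in ("ibrutinib", "ctp")},
            monitoring_costs=dataclasses.replace(
                params.monitoring_costs,
                pre_progression_ibrutinib=0.0, pre_progression_ctp=0.0,
                subsequent=0.0, bsc=0.0,
            ),
            cost_scales=dataclasses.replace(
                params.cost_scales,
                ctp_drug=0.0, ctp_admin=0.0, post_progression_regimen=0.0,
                ibrutinib_dose_intensity=0.0,
            ),
        )
        trace = run_arm_trace(zero, ARM_IBRUTINIB)
        costs = accumulate_costs(trace, zero, ARM_IBRUTINIB, 0.03)
        assert costs.total == 0.0
        assert costs.undiscounted_total == 0.0

    def test_component_additivity(self, base_result):
        for arm in (base_result.arm_a, base_result.arm_b):
            c = arm.costs
            assert c.total == pytest.approx(
                c.drug + c.administration + c.sae + c.post_progression, abs=1e-6
            )

    def test_undiscounted_at_least_discounted(self, base_result):
        for arm in (base_result.arm_a, base_result.arm_b):
            assert arm.costs.undiscounted_total >= arm.costs.total

    @pytest.mark.parametrize("arm", [ARM_IBRUTINIB, ARM_CTP])
    def test_cost_linearity_under_price_scaling(self, params, arm):
        """Scaling every unit price, tariff and bundle by alpha scales
        every component by alpha exactly; the trace is untouched."""
        from helpers import scale_all_prices

        alpha = 1.7
        scaled = scale_all_prices(params, alpha)
        trace = run_arm_trace(params, arm)
        base = accumulate_costs(trace, params, arm, 0.03)
        up = accumulate_costs(trace, scaled, arm, 0.03)
        for f in ("drug", "administration", "sae", "post_progression"):
            assert getattr(up, f) == pytest.approx(alpha * getattr(base, f), rel=1e-12)

    def test_components_non_increasing_in_cost_discount_rate(self, params):
        trace = run_arm_trace(params, ARM_CTP)
        rates = (0.0, 0.03, 0.06, 0.1)
        results = [accumulate_costs(trace, params, ARM_CTP, r) for r in rates]
        for f in ("drug", "administration", "sae", "post_progression"):
            vals = [getattr(r, f) for r in results]
            assert all(b <= a for a, b in zip(vals, vals[1:]))
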