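"""Activity-based costing of the care pathways.

Per-cycle costs are attached to health states and accumulated over the
cohort trace with discounting.  The four reported components mirror the
published cost layout:

* ``drug`` — acquisition cost of the initial-treatment regimen(s),
* ``administration`` — day-hospital tariff per IV administration day,
* ``sae`` — severe-adverse-event management (DRG inpatient tariffs)
  plus the pre-progression monitoring bundle (the published layout has
  no separate monitoring row, so pre-progression monitoring is folded
  here and post-progression monitoring into ``post_progression``),
* ``post_progression`` — everything accrued in the subsequent-line and
  BSC states (mix-weighted regimen costs, administration, monitoring).

IV doses are rounded up to whole vials per administration; oral drugs
are costed per capsule-day.  Internal arithmetic is full precision;
whole-euro rounding happens only at render time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace, HealthState, N_STATES, discount_factors
from .params import (
    ARM_CTP,
    ARM_IBRUTINIB,
    DrugPriceTable,
    ParameterSet,
    PatientProfile,
    Regimen,
    TariffTable,
)

ADMIN_TARIFF_ITEM = "chemotherapy_administration"

_COMPONENTS = ("drug", "administration", "sae", "post_progression")


class CostingError(ValueError):
    pass


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-arm cost components (EUR)."""

    drug: float
    administration: float
    sae: float
    post_progression: float
    undiscounted_total: float

    @property
    def total(self) -> float:
        return self.drug + self.administration + self.sae + self.post_progression


def _dose_mg(component, patient: PatientProfile) -> float:
    basis = component.dose_basis
    if basis == "flat_mg" or basis == "mg_per_day":
        return component.dose_value
    if basis == "mg_per_m2":
        return component.dose_value * patient.body_surface_area_m2
    if basis == "mg_per_kg":
        return component.dose_value * patient.weight_kg
    raise CostingError(f"unknown dose basis {basis!r}")


def drug_cost_per_cycle(
    regimen: Regimen, prices: DrugPriceTable, patient: PatientProfile
) -> float:
    """Acquisition cost of one model cycle of a regimen.

    Each administration (or treatment day for daily oral dosing) is
    costed as ceil(dose / unit size) units at the unit price.
    """
    total = 0.0
    for c in regimen.components:
        if c.drug not in prices:
            raise CostingError(f"no price for drug {c.drug!r}")
        price = prices[c.drug]
        dose = _dose_mg(c, patient)
        units = math.ceil(dose / price.unit_mg - 1e-9)
        total += units * price.unit_cost_eur * c.administrations_per_cycle
    return total


def administration_cost_per_cycle(regimen: Regimen, tariffs: TariffTable) -> float:
    """Day-hospital administration tariff times IV days per cycle."""
    if regimen.iv_days_per_cycle == 0:
        return 0.0
    return tariffs[ADMIN_TARIFF_ITEM].tariff_eur * regimen.iv_days_per_cycle


def sae_cost_per_cycle(arm: str, sae_rates: dict, tariffs: TariffTable) -> float:
    """Expected SAE management cost per cycle on active treatment."""
    sae_tariffs = tariffs.sae_items()
    total = 0.0
    for item, rate in sae_rates[arm].items():
        if item not in sae_tariffs:
            raise CostingError(f"SAE rate for untariffed event {item!r}")
        if not (0.0 <= rate <= 1.0):
            raise CostingError(f"SAE rate for {item!r} outside [0, 1]")
        total += rate * sae_tariffs[item]
    return total


def _initial_treatment_costs(params: ParameterSet, arm: str) -> tuple[float, float]:
    """(drug, administration) per cycle in the initial-treatment state."""
    if arm == ARM_IBRUTINIB:
        reg = params.regimen(ARM_IBRUTINIB)
        return (
            drug_cost_per_cycle(reg, params.prices, params.patient)
            * params.cost_scales.ibrutinib_dose_intensity,
            administration_cost_per_cycle(reg, params.tariffs),
        )
    if arm == ARM_CTP:
        drug = 0.0
        admin = 0.0
        for rid, share in params.mix.pre_shares.items():
            reg = params.regimen(rid)
            drug += share * drug_cost_per_cycle(reg, params.prices, params.patient)
            admin += share * administration_cost_per_cycle(reg, params.tariffs)
        return (
            drug * params.cost_scales.ctp_drug,
            admin * params.cost_scales.ctp_admin,
        )
    raise CostingError(f"unknown arm {arm!r}")


def post_progression_regimen_cost_per_cycle(params: ParameterSet) -> float:
    """Mix-weighted subsequent-line regimen cost (drug + administration).

    Weighted by the post-progression column among actively treated
    progressors; identical for both arms (progressors of either arm
    receive the same subsequent pathways).
    """
    total = 0.0
    for rid, w in params.mix.post_shares_normalized().items():
        reg = params.regimen(rid)
        total += w * (
            drug_cost_per_cycle(reg, params.prices, params.patient)
            + administration_cost_per_cycle(reg, params.tariffs)
        )
    return total * params.cost_scales.post_progression_regimen


def _initial_drug_admin_profile(
    params: ParameterSet, arm: str, n_cycles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (drug, administration) cost arrays for the initial state.

    The initial-treatment state is entered only at model start, so time
    in state equals model time: a fixed treatment course of K cycles
    (``max_treatment_cycles``) accrues acquisition and administration
    cost in cycles 0..K-1 only.  Ibrutinib (course of ``None``) is
    dosed continuously until progression.
    """
    drug = np.zeros(n_cycles)
    admin = np.zeros(n_cycles)
    if arm == ARM_IBRUTINIB:
        reg = params.regimen(ARM_IBRUTINIB)
        drug += (
            drug_cost_per_cycle(reg, params.prices, params.patient)
            * params.cost_scales.ibrutinib_dose_intensity
        )
        admin += administration_cost_per_cycle(reg, params.tariffs)
        return drug, admin
    if arm != ARM_CTP:
        raise CostingError(f"unknown arm {arm!r}")
    for rid, share in params.mix.pre_shares.items():
        reg = params.regimen(rid)
        k = n_cycles if reg.max_treatment_cycles is None else min(
            reg.max_treatment_cycles, n_cycles
        )
        drug[:k] += share * drug_cost_per_cycle(reg, params.prices, params.patient)
        admin[:k] += share * administration_cost_per_cycle(reg, params.tariffs)
    drug *= params.cost_scales.ctp_drug
    admin *= params.cost_scales.ctp_admin
    return drug, admin


def on_treatment_weight(params: ParameterSet, arm: str, n_cycles: int) -> np.ndarray:
    """Fraction of the initial-state cohort still on its treatment course.

    1 throughout for ibrutinib (continuous dosing); for CTP it is the
    mix-share-weighted indicator of the per-regimen course windows.
    """
    if arm == ARM_IBRUTINIB:
        return np.ones(n_cycles)
    w = np.zeros(n_cycles)
    for rid, share in params.mix.pre_shares.items():
        reg = params.regimen(rid)
        k = n_cycles if reg.max_treatment_cycles is None else min(
            reg.max_treatment_cycles, n_cycles
        )
        w[:k] += share
    return w


def cost_profile(
    params: ParameterSet, arm: str, n_cycles: int, subsequent_lines_active: bool = True
) -> np.ndarray:
    """Per-cycle per-state cost components, shape (cycles, 5 states, 4).

    Component order: drug, administration, sae, post_progression.
    All initial-state costs are tied to active treatment: for fixed
    chemo-immunotherapy courses, acquisition, administration, SAE
    management and monitoring accrue during the course window
    (watch-and-wait afterwards); for continuous ibrutinib dosing they
    run until progression.  ``subsequent_lines_active=False``
    zeroes subsequent-line regimen costs (the 'no subsequent lines'
    scenario) but keeps monitoring.
    """
    mon = params.monitoring_costs
    profile = np.zeros((n_cycles, N_STATES, len(_COMPONENTS)))
    drug, admin = _initial_drug_admin_profile(params, arm, n_cycles)
    sae = sae_cost_per_cycle(arm, params.sae_rates, params.tariffs)
    mon_pre = (
        mon.pre_progression_ibrutinib if arm == ARM_IBRUTINIB else mon.pre_progression_ctp
    )
    I = HealthState.INITIAL_TREATMENT
    profile[:, I, 0] = drug
    profile[:, I, 1] = admin
    profile[:, I, 2] = (sae + mon_pre) * on_treatment_weight(params, arm, n_cycles)

    sub_regimen = (
        post_progression_regimen_cost_per_cycle(params) if subsequent_lines_active else 0.0
    )
    profile[:, HealthState.SUBSEQUENT_1, 3] = sub_regimen + mon.subsequent
    profile[:, HealthState.SUBSEQUENT_2, 3] = sub_regimen + mon.subsequent
    profile[:, HealthState.BSC, 3] = mon.bsc
    return profile


def state_cycle_cost(
    params: ParameterSet, arm: str, state: HealthState, cycle: int = 0,
    subsequent_lines_active: bool = True,
) -> float:
    """Total cost (EUR) of occupying ``state`` during ``cycle``."""
    profile = cost_profile(params, arm, cycle + 1, subsequent_lines_active)
    return float(profile[cycle, state].sum())


def accumulate_costs(
    trace: CohortTrace,
    params: ParameterSet,
    arm: str,
    rate: float,
    subsequent_lines_active: bool = True,
) -> CostBreakdown:
    """Discounted component totals over a cohort trace."""
    n = trace.n_cycles
    profile = cost_profile(params, arm, n, subsequent_lines_active)
    occ = trace.occupancy[:-1]  # cycle-start membership
    df = discount_factors(n, rate, trace.cycle_length_years)
    per_cycle = np.einsum("ks,ksc->kc", occ, profile)
    discounted = df @ per_cycle
    undiscounted = per_cycle.sum(axis=0)
    return CostBreakdown(
        drug=float(discounted[0]),
        administration=float(discounted[1]),
        sae=float(discounted[2]),
        post_progression=float(discounted[3]),
        undiscounted_total=float(undiscounted.sum()),
    )
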