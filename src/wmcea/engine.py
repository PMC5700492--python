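"""Five-state Markov cohort engine.

States: initial treatment, first subsequent treatment, second
subsequent treatment, best supportive care (BSC), death.  The cohort
enters in the initial-treatment state; progression triggers a move to
the next treatment line (70% of progressors) or directly to BSC (30%,
the share receiving no further active regimen); death is absorbing and
can occur from any state.

Within a cycle, death and progression compete: the death probability q
is applied first and progression p is resolved among survivors, so the
per-cycle move masses from a pre-BSC state are q to death, (1-q)*p
split 70/30 onward, and (1-q)*(1-p) staying.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np

from .params import POST_PROGRESSION_ACTIVE_SHARE, ARM_CTP, ARM_IBRUTINIB, ParameterSet
from .survival import (
    cycle_transition_probabilities,
    derive_comparator_curve,
)


class HealthState(IntEnum):
    INITIAL_TREATMENT = 0
    SUBSEQUENT_1 = 1
    SUBSEQUENT_2 = 2
    BSC = 3
    DEATH = 4


N_STATES = len(HealthState)
INITIAL_DISTRIBUTION = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy fractions per cycle: matrix of shape (cycles+1, 5).

    Row k is the state distribution at the *start* of cycle k.
    """

    occupancy: np.ndarray
    cycle_length_years: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0]) * self.cycle_length_years

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, HealthState.DEATH]

    def validate(self, tol: float = 1e-12) -> None:
        if np.any(self.occupancy < -tol):
            raise ValueError("negative occupancy")
        if np.max(np.abs(self.occupancy.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("trace rows do not sum to 1")
        death = self.occupancy[:, HealthState.DEATH]
        if np.any(np.diff(death) < -tol):
            raise ValueError("death occupancy must be non-decreasing")

    def to_csv(self, path: str | Path) -> None:
        header = "cycle,year," + ",".join(s.name.lower() for s in HealthState)
        rows = np.column_stack([np.arange(len(self.years)), self.years, self.occupancy])
        np.savetxt(path, rows, delimiter=",", header=header, comments="",
                   fmt=["%d", "%.6f"] + ["%.10f"] * N_STATES)


@dataclass(frozen=True)
class LifeYearResult:
    discounted_ly: float
    undiscounted_ly: float


def _per_cycle_death_probs(params: ParameterSet, extra_hazard_per_year: float = 0.0) -> np.ndarray:
    """Background (plus optional excess) per-cycle death probability by cycle.

    The cohort ages from ``start_age``; the annual q is read at the
    (floored) attained age and converted to the cycle length.
    """
    s = params.settings
    delta = s.cycle_length_years
    ages = s.start_age + np.arange(s.n_cycles) * delta
    q_annual = np.array(
        [params.background_mortality.annual_probability(a) for a in ages]
    )
    q_cycle = 1.0 - (1.0 - q_annual) ** delta
    if extra_hazard_per_year > 0.0:
        q_cycle = 1.0 - (1.0 - q_cycle) * np.exp(-extra_hazard_per_year * delta)
    return q_cycle


def build_transition_schedule(
    params: ParameterSet,
    arm: str,
    pfs_curve=None,
    dwell_hazard_multiplier: float = 1.0,
) -> np.ndarray:
    """Per-cycle 5x5 row-stochastic transition matrices for one arm.

    ``pfs_curve`` overrides the arm's progression curve (used by the
    log-logistic projection scenario); ``dwell_hazard_multiplier``
    scales the subsequent-line exit hazards (post-progression efficacy
    scenarios: +20% efficacy = hazards / 1.2).
    """
    s = params.settings
    delta = s.cycle_length_years
    n = s.n_cycles

    if pfs_curve is None:
        pfs_curve = params.pfs_ibrutinib
        if arm == ARM_CTP:
            pfs_curve = derive_comparator_curve(params.pfs_ibrutinib, params.hr)
    elif arm == ARM_CTP:
        pfs_curve = derive_comparator_curve(pfs_curve, params.hr)

    p_prog = cycle_transition_probabilities(pfs_curve, n, delta)

    if arm == ARM_IBRUTINIB:
        q_initial = _per_cycle_death_probs(params)
    elif arm == ARM_CTP:
        q_initial = _per_cycle_death_probs(
            params, params.excess_mortality.ctp_pre_progression_per_year
        )
    else:
        raise ValueError(f"unknown arm {arm!r}")

    q_bg = _per_cycle_death_probs(params)
    q_bsc = _per_cycle_death_probs(params, params.excess_mortality.bsc_per_year)

    dw = params.post_progression_dwell
    m = dwell_hazard_multiplier
    p_sub1 = 1.0 - np.exp(-dw.sub1_hazard_per_year * m * delta)
    p_sub2 = 1.0 - np.exp(-dw.sub2_hazard_per_year * m * delta)

    a = POST_PROGRESSION_ACTIVE_SHARE
    mats = np.zeros((n, N_STATES, N_STATES))
    I, S1, S2, B, D = (int(st) for st in HealthState)

    mats[:, I, D] = q_initial
    mats[:, I, S1] = (1 - q_initial) * p_prog * a
    mats[:, I, B] = (1 - q_initial) * p_prog * (1 - a)
    mats[:, I, I] = (1 - q_initial) * (1 - p_prog)

    mats[:, S1, D] = q_bg
    mats[:, S1, S2] = (1 - q_bg) * p_sub1 * a
    mats[:, S1, B] = (1 - q_bg) * p_sub1 * (1 - a)
    mats[:, S1, S1] = (1 - q_bg) * (1 - p_sub1)

    mats[:, S2, D] = q_bg
    mats[:, S2, B] = (1 - q_bg) * p_sub2
    mats[:, S2, S2] = (1 - q_bg) * (1 - p_sub2)

    mats[:, B, D] = q_bsc
    mats[:, B, B] = 1 - q_bsc

    mats[:, D, D] = 1.0

    if np.any(mats < 0) or np.any(mats > 1):
        raise ValueError("transition probabilities outside [0, 1]")
    return mats


def run_cohort(schedule: np.ndarray, cycles: int | None = None,
               initial: np.ndarray | None = None,
               cycle_length_years: float = 1.0 / 13.0) -> CohortTrace:
    """Propagate the cohort through the per-cycle transition matrices."""
    if cycles is None:
        cycles = schedule.shape[0]
    if schedule.shape[0] < cycles:
        raise ValueError("schedule shorter than requested number of cycles")
    if initial is None:
        initial = INITIAL_DISTRIBUTION
    occ = np.empty((cycles + 1, N_STATES))
    occ[0] = initial
    for k in range(cycles):
        occ[k + 1] = occ[k] @ schedule[k]
    trace = CohortTrace(occupancy=occ, cycle_length_years=cycle_length_years)
    trace.validate()
    return trace


def discount_factors(n_cycles: int, rate: float, cycle_length_years: float) -> np.ndarray:
    """(1+rate)^(-k*delta) for cycle starts k = 0..n-1."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    k = np.arange(n_cycles)
    return (1.0 + rate) ** (-k * cycle_length_years)


def life_years(trace: CohortTrace, rate: float) -> LifeYearResult:
    """Discounted and undiscounted life years from a cohort trace.

    Membership is counted at cycle start (no half-cycle correction):
    LY = sum_k alive_k * delta * (1+rate)^(-k*delta).
    """
    delta = trace.cycle_length_years
    alive = trace.alive[:-1]
    df = discount_factors(trace.n_cycles, rate, delta)
    return LifeYearResult(
        discounted_ly=float(np.sum(alive * delta * df)),
        undiscounted_ly=float(np.sum(alive * delta)),
    )


def run_arm_trace(params: ParameterSet, arm: str, **kwargs) -> CohortTrace:
    """Convenience: schedule + cohort run for one arm."""
    schedule = build_transition_schedule(params, arm, **kwargs)
    return run_cohort(
        schedule, cycle_length_years=params.settings.cycle_length_years
    )
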