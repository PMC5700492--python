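"""Parametric time-to-event curves and transition-probability conversion.

Progression-free survival of the ibrutinib arm is modelled with a
parametric curve (Weibull in the base case, log-logistic as a scenario)
and the comparator arm is derived from it under proportional hazards
using the published hazard ratio.  Curves are converted to per-cycle
transition probabilities for the cohort engine; background mortality
comes from an annual life table.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SurvivalCurve",
    "ProportionalHazardsCurve",
    "MortalityTable",
    "survival_at",
    "derive_comparator_curve",
    "cycle_transition_probability",
    "background_death_probability",
    "match_loglogistic",
]

_FAMILIES = ("weibull", "loglogistic")


@dataclass(frozen=True)
class SurvivalCurve:
    """Parametric survival function.

    weibull:      S(t) = exp(-(t/scale)^shape)
    loglogistic:  S(t) = 1 / (1 + (t/scale)^shape)

    ``scale`` is in years; ``shape`` is dimensionless.  Both > 0.
    """

    family: str
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")

    def survival(self, t):
        return survival_at(self, t)


def survival_at(curve, t):
    """S(t) for scalar or array ``t`` (years); raises on negative times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival_at requires t >= 0")
    z = (t / curve.scale) ** curve.shape
    if curve.family == "weibull":
        out = np.exp(-z)
    elif curve.family == "loglogistic":
        out = 1.0 / (1.0 + z)
    else:  # ProportionalHazardsCurve delegates before reaching here
        raise ValueError(f"unknown survival family {curve.family!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProportionalHazardsCurve:
    """Survival curve obtained by scaling another curve's hazard.

    With base hazard h(t) and multiplier m, S(t) = S_base(t)**m.
    """

    base: SurvivalCurve
    hazard_multiplier: float

    def __post_init__(self) -> None:
        if self.hazard_multiplier <= 0:
            raise ValueError("hazard multiplier must be > 0")

    def survival(self, t):
        s = self.base.survival(t)
        return s ** self.hazard_multiplier


def derive_comparator_curve(base: SurvivalCurve, hr) -> ProportionalHazardsCurve:
    """CTP PFS from the ibrutinib PFS under proportional hazards.

    The published HR is ibrutinib vs. CTP, so the comparator hazard is
    the base hazard divided by the HR: S_ctp(t) = S_ibr(t)**(1/HR).
    ``hr`` may be a :class:`~wmcea.params.HazardRatio` or a plain float.
    """
    point = getattr(hr, "point", hr)
    if point <= 0:
        raise ValueError("hazard ratio must be > 0")
    return ProportionalHazardsCurve(base=base, hazard_multiplier=1.0 / point)


def cycle_transition_probability(curve, cycle_index: int, cycle_length: float) -> float:
    """Conditional event probability within one cycle.

    p_k = 1 - S((k+1)*delta) / S(k*delta); returns 1 once S has reached 0.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    s0 = curve.survival(cycle_index * cycle_length)
    if s0 <= 0.0:
        return 1.0
    s1 = curve.survival((cycle_index + 1) * cycle_length)
    p = 1.0 - s1 / s0
    return min(max(p, 0.0), 1.0)


def cycle_transition_probabilities(curve, n_cycles: int, cycle_length: float) -> np.ndarray:
    """Vectorised ``cycle_transition_probability`` for cycles 0..n-1."""
    t = np.arange(n_cycles + 1) * cycle_length
    s = np.asarray(curve.survival(t), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - np.where(s[:-1] > 0.0, s[1:] / s[:-1], 0.0)
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True, eq=False)
class MortalityTable:
    """Annual death probability by integer age.

    The shipped table is synthetic (Gompertz–Makeham hazard with Italian
    general-population magnitudes); the published analysis names no life
    table, only that pre-progression mortality on ibrutinib equals
    general-population mortality.
    """

    ages: np.ndarray
    annual_q: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ValueError("annual probabilities must be in [0, 1]")
        if len(self.ages) != len(self.annual_q):
            raise ValueError("ages and annual_q length mismatch")

    def __eq__(self, other) -> bool:
        if not isinstance(other, MortalityTable):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(
            self.annual_q, other.annual_q
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(ages=data["age"].astype(int), annual_q=data["annual_q"].astype(float))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("age,annual_q\n")
            for a, q in zip(self.ages, self.annual_q):
                fh.write(f"{int(a)},{q:.6f}\n")

    @classmethod
    def synthetic_gompertz_makeham(
        cls,
        age_min: int = 40,
        age_max: int = 110,
        makeham: float = 2e-4,
        level: float = 3e-5,
        slope: float = 0.09,
    ) -> "MortalityTable":
        """Synthetic default life table: q(a) = min(1, c + b*exp(k*a))."""
        ages = np.arange(age_min, age_max + 1)
        q = np.minimum(makeham + level * np.exp(slope * ages), 1.0)
        return cls(ages=ages, annual_q=q)

    def annual_probability(self, age: float) -> float:
        """Annual q at (floored) age, clamped to the table's age range."""
        idx = int(np.floor(age)) - int(self.ages[0])
        idx = min(max(idx, 0), len(self.ages) - 1)
        return float(self.annual_q[idx])


def background_death_probability(table: MortalityTable, age: float, cycle_length: float) -> float:
    """Per-cycle death probability 1 - (1 - q_annual)^cycle_length."""
    q = table.annual_probability(age)
    return 1.0 - (1.0 - q) ** cycle_length


def match_loglogistic(
    weibull: SurvivalCurve, t1: float = 1.0, t2: float = 3.0
) -> SurvivalCurve:
    """Log-logistic curve agreeing with a Weibull at two time points.

    Used by the 'log-logistic projection' scenario: the published model
    reports an alternative projection but not its parameters, so the
    scenario curve is anchored to the base-case curve at ``t1`` and
    ``t2`` years.  In the log-logistic family the odds of having
    progressed, (1-S)/S = (t/scale)^shape, are log-linear in time, so a
    two-point match has a closed form.
    """
    if weibull.family != "weibull":
        raise ValueError("match_loglogistic expects a weibull base curve")
    s1, s2 = weibull.survival(t1), weibull.survival(t2)
    odds1, odds2 = (1.0 - s1) / s1, (1.0 - s2) / s2
    shape = np.log(odds2 / odds1) / np.log(t2 / t1)
    scale = t1 / odds1 ** (1.0 / shape)
    return SurvivalCurve(family="loglogistic", shape=float(shape), scale=float(scale))
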