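"""Parametric curves, proportional hazards and probability conversion."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmcea.survival import (
    MortalityTable,
    SurvivalCurve,
    background_death_probability,
    cycle_transition_probabilities,
    cycle_transition_probability,
    derive_comparator_curve,
    match_loglogistic,
    survival_at,
)

DELTA = 1.0 / 13.0


@pytest.mark.parametrize(
    "curve, t, expected",
    [
        (SurvivalCurve("weibull", 1.7, 3.2), 0.0, 1.0),
        (SurvivalCurve("loglogistic", 0.9, 2.0), 0.0, 1.0),
        # shape-1 Weibull is exponential: S(2) = exp(-2/2)
        (SurvivalCurve("weibull", 1.0, 2.0), 2.0, math.exp(-1.0)),
        # log-logistic median is the scale parameter
        (SurvivalCurve("loglogistic", 1.0, 1.0), 1.0, 0.5),
    ],
)
def test_survival_closed_forms(curve, t, expected):
    assert survival_at(curve, t) == pytest.approx(expected, abs=1e-12)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        survival_at(SurvivalCurve("weibull", 1.0, 1.0), -0.1)
    with pytest.raises(ValueError):
        SurvivalCurve("weibull", -1.0, 1.0)


class TestProportionalHazards:
    def test_unit_hazard_ratio_is_identity(self):
        base = SurvivalCurve("weibull", 1.4, 3.0)
        same = derive_comparator_curve(base, 1.0)
        t = np.linspace(0, 15, 50)
        assert np.allclose(same.survival(t), base.survival(t), atol=1e-14)

    def test_power_relation_from_hazard_ratio(self):
        # HR 0.25 (base more effective): comparator survival = base**4
        base = SurvivalCurve("weibull", 1.0, 1.0)
        comp = derive_comparator_curve(base, 0.25)
        t = -math.log(0.8)  # S_base(t) = 0.8
        assert comp.survival(t) == pytest.approx(0.8**4, abs=1e-12)
        # HR 0.5: S_base = 0.49 -> comparator 0.49**2
        comp2 = derive_comparator_curve(base, 0.5)
        t2 = -math.log(0.49)
        assert comp2.survival(t2) == pytest.approx(0.2401, abs=1e-12)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ValueError):
            derive_comparator_curve(SurvivalCurve("weibull", 1.0, 1.0), 0.0)

    def test_comparator_preserves_anchoring_and_monotonicity(self):
        base = SurvivalCurve("weibull", 1.6, 4.0)
        comp = derive_comparator_curve(base, 0.25)
        t = np.linspace(0, 30, 400)
        s = comp.survival(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) < 0)
        assert np.all(s <= base.survival(t) + 1e-15)

    def test_restricted_mean_survival_shrinks_when_hr_below_one(self):
        # brute-force numeric integration over the horizon as oracle
        base = SurvivalCurve("weibull", 1.6, 4.0)
        comp = derive_comparator_curve(base, 0.25)
        t = np.linspace(0, 15, 20001)
        rmst_base = np.trapezoid(base.survival(t), t)
        rmst_comp = np.trapezoid(comp.survival(t), t)
        assert rmst_comp < rmst_base


class TestCycleTransitionProbability:
    def test_constant_survival_gives_zero(self):
        class Flat:
            def survival(self, t):
                return np.full_like(np.asarray(t, dtype=float), 0.7)

        assert cycle_transition_probability(Flat(), 5, DELTA) == 0.0

    def test_exponential_is_memoryless(self):
        curve = SurvivalCurve("weibull", 1.0, 2.5)  # constant hazard 1/2.5
        expected = 1.0 - math.exp(-DELTA / 2.5)
        for k in (0, 7, 100):
            assert cycle_transition_probability(curve, k, DELTA) == pytest.approx(
                expected, abs=1e-14
            )

    def test_increasing_weibull_hazard_gives_increasing_probabilities(self):
        curve = SurvivalCurve("weibull", 2.3, 4.8)
        p = [cycle_transition_probability(curve, k, DELTA) for k in range(51)]
        assert all(b > a for a, b in zip(p, p[1:]))

    def test_exhausted_survival_returns_one(self):
        class Dead:
            def survival(self, t):
                return np.where(np.asarray(t, dtype=float) < 1.0, 1.0, 0.0)

        assert cycle_transition_probability(Dead(), 20, DELTA) == 1.0


@settings(max_examples=30, deadline=None)
@given(
    family=st.sampled_from(["weibull", "loglogistic"]),
    shape=st.floats(0.5, 3.0),
    scale=st.floats(0.5, 12.0),
)
def test_per_cycle_probabilities_reconstruct_the_curve(family, shape, scale):
    """prod(1 - p_k) over k cycles equals S(k*delta) to 1e-12."""
    curve = SurvivalCurve(family, shape, scale)
    n = 195
    p = cycle_transition_probabilities(curve, n, DELTA)
    rebuilt = np.cumprod(1.0 - p)
    expected = curve.survival(np.arange(1, n + 1) * DELTA)
    assert np.max(np.abs(rebuilt - expected)) < 1e-12


class TestMortality:
    table = MortalityTable(ages=np.arange(60, 70), annual_q=np.full(10, 0.02))

    def test_zero_rate_gives_zero(self):
        t = MortalityTable(ages=np.arange(60, 70), annual_q=np.zeros(10))
        assert background_death_probability(t, 65, DELTA) == 0.0

    def test_annual_to_cycle_conversion(self):
        got = background_death_probability(self.table, 65, DELTA)
        assert got == pytest.approx(1.0 - 0.98 ** (1.0 / 13.0), abs=1e-12)

    def test_certain_death_stays_certain(self):
        t = MortalityTable(ages=np.arange(60, 70), annual_q=np.ones(10))
        assert background_death_probability(t, 65, 1.0) == 1.0

    def test_age_outside_table_clamped(self):
        assert self.table.annual_probability(30) == 0.02
        assert self.table.annual_probability(120) == 0.02

    def test_synthetic_table_non_decreasing_above_40(self):
        t = MortalityTable.synthetic_gompertz_makeham()
        assert np.all(np.diff(t.annual_q) >= 0)
        assert np.all((t.annual_q >= 0) & (t.annual_q <= 1))


def test_matched_loglogistic_agrees_at_anchor_points():
    base = SurvivalCurve("weibull", 2.3, 4.8)
    ll = match_loglogistic(base, t1=1.0, t2=3.0)
    assert ll.family == "loglogistic"
    for t in (1.0, 3.0):
        assert ll.survival(t) == pytest.approx(base.survival(t), abs=1e-12)
    # heavier tail than the Weibull beyond the anchors
    assert ll.survival(12.0) > base.survival(12.0)
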