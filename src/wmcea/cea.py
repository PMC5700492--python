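"""Incremental cost-effectiveness analysis: the base-case table and ICER.

Combines per-arm life years and discounted costs into increments and
the incremental cost-effectiveness ratio (EUR per life-year gained).
The ICER is always computed from unrounded deltas; whole-euro and
two-decimal rounding happen only when a report is rendered.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .costing import CostBreakdown, accumulate_costs
from .engine import CohortTrace, LifeYearResult, life_years, run_arm_trace
from .params import ARM_CTP, ARM_IBRUTINIB, ParameterSet

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ArmResult:
    arm: str
    life_years: LifeYearResult
    costs: CostBreakdown
    trace: Optional[CohortTrace] = None


@dataclass(frozen=True)
class CEAResult:
    arm_a: ArmResult  # intervention (ibrutinib)
    arm_b: ArmResult  # comparator (CTP)

    @property
    def delta_cost(self) -> float:
        return self.arm_a.costs.total - self.arm_b.costs.total

    @property
    def delta_ly(self) -> float:
        return self.arm_a.life_years.discounted_ly - self.arm_b.life_years.discounted_ly

    @property
    def dominance(self) -> Optional[str]:
        dc, dly = self.delta_cost, self.delta_ly
        if dly > 0 and dc <= 0:
            return DOMINANT
        if dly < 0 and dc >= 0:
            return DOMINATED
        if dly == 0:
            return UNDEFINED if dc != 0 else None
        return None

    @property
    def icer(self) -> Optional[float]:
        """EUR per LYG from unrounded deltas; None when ΔLY = 0."""
        if self.delta_ly == 0:
            return None
        return self.delta_cost / self.delta_ly


def compute_icer(a: ArmResult, b: ArmResult) -> CEAResult:
    return CEAResult(arm_a=a, arm_b=b)


def run_arm(
    params: ParameterSet,
    arm: str,
    keep_trace: bool = False,
    subsequent_lines_active: bool = True,
    **schedule_kwargs,
) -> ArmResult:
    """Trace, life years and costs for one arm under the given settings."""
    trace = run_arm_trace(params, arm, **schedule_kwargs)
    ly = life_years(trace, params.settings.discount_rate_effects)
    costs = accumulate_costs(
        trace,
        params,
        arm,
        params.settings.discount_rate_costs,
        subsequent_lines_active=subsequent_lines_active,
    )
    return ArmResult(
        arm=arm, life_years=ly, costs=costs, trace=trace if keep_trace else None
    )


def run_base_case(
    params: ParameterSet,
    keep_traces: bool = False,
    subsequent_lines_active: bool = True,
    **schedule_kwargs,
) -> CEAResult:
    """End-to-end: schedules → traces → life years → costs → increments."""
    a = run_arm(
        params, ARM_IBRUTINIB, keep_trace=keep_traces,
        subsequent_lines_active=subsequent_lines_active, **schedule_kwargs,
    )
    b = run_arm(
        params, ARM_CTP, keep_trace=keep_traces,
        subsequent_lines_active=subsequent_lines_active, **schedule_kwargs,
    )
    return compute_icer(a, b)


def result_frame(result: CEAResult) -> pd.DataFrame:
    """The base-case table as a DataFrame (unrounded values)."""
    a, b = result.arm_a, result.arm_b
    rows = [
        ("Life Years (discounted)", a.life_years.discounted_ly,
         b.life_years.discounted_ly, result.delta_ly),
        ("Drug cost", a.costs.drug, b.costs.drug, a.costs.drug - b.costs.drug),
        ("Administration cost", a.costs.administration, b.costs.administration,
         a.costs.administration - b.costs.administration),
        ("Serious Adverse Events costs", a.costs.sae, b.costs.sae,
         a.costs.sae - b.costs.sae),
        ("Total post-progression costs", a.costs.post_progression,
         b.costs.post_progression, a.costs.post_progression - b.costs.post_progression),
        ("Total Costs", a.costs.total, b.costs.total, result.delta_cost),
    ]
    return pd.DataFrame(rows, columns=["variable", "ibrutinib", "ctp", "increment"])


def render_report(result: CEAResult, fmt: str = "text") -> str:
    """Deterministic report: whole-euro costs, 2-decimal LY.

    The ICER row is computed from unrounded deltas (a footnote states
    this); ``fmt`` is 'text' or 'csv' and both carry identical numbers.
    """
    df = result_frame(result).copy()
    ly_mask = df["variable"].str.startswith("Life Years")
    for col in ("ibrutinib", "ctp", "increment"):
        df[col] = [
            round(v, 2) if is_ly else float(round(v))
            for v, is_ly in zip(df[col], ly_mask)
        ]
    icer = result.icer
    dominance_text = (
        result.dominance if icer is None or result.dominance in (DOMINANT, DOMINATED)
        else None
    )
    icer_text = dominance_text if dominance_text else f"{icer:,.0f}"
    if fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        cell = dominance_text if dominance_text else f"{icer:.0f}"
        buf.write(f"ICER EUR/LYG (ibrutinib vs CTP),{cell},,\n")
        return buf.getvalue()
    if fmt == "text":
        lines = [f"{'Variable':<32}{'Ibrutinib':>14}{'CTP':>14}{'Increment':>14}"]
        for _, r in df.iterrows():
            is_ly = r["variable"].startswith("Life Years")
            spec = ",.2f" if is_ly else ",.0f"
            lines.append(
                f"{r['variable']:<32}{r['ibrutinib']:>{14}{spec}}"
                f"{r['ctp']:>{14}{spec}}{r['increment']:>{14}{spec}}"
            )
        lines.append(f"{'ICER EUR/LYG (ibrutinib vs CTP)':<32}{icer_text:>14}")
        lines.append("Note: ICER computed from unrounded increments.")
        return "\n".join(lines)
    raise ValueError(f"unknown report format {fmt!r}")
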