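"""Deterministic and probabilistic sensitivity analysis.

The deterministic analysis (DSA) is a one-way scenario table: each
scenario replaces one input (time horizon, discount rates, projection
family, hazard ratio, subsequent-line costing, post-progression
efficacy, ibrutinib price) and reruns the full pipeline.  The
probabilistic analysis (PSA) jointly samples all uncertain inputs —
the sampling distributions are not published, so the defaults are the
conventional choices (lognormal hazard ratio matched to the printed
95% CI, gamma cost bundles, beta incidences, lognormal survival and
dwell parameters) and every hyperparameter is configurable.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cea import CEAResult, run_base_case
from .params import (
    ARM_IBRUTINIB,
    CostScales,
    DrugPrice,
    DrugPriceTable,
    ExcessMortality,
    MonitoringCosts,
    ParameterSet,
    PostProgressionDwell,
)
from .survival import SurvivalCurve, match_loglogistic


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Deterministic one-way scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSAScenario:
    """One-way scenario: a set of declarative overrides on the base inputs.

    ``settings`` maps ModelSettings field names to alternative values.
    The remaining fields cover the structural toggles of the published
    scenario table.  Applying a scenario never mutates the base
    parameter set (all domain types are immutable).
    """

    scenario_id: str
    description: str
    settings: dict = field(default_factory=dict)
    hr_point: Optional[float] = None
    ibrutinib_price_multiplier: Optional[float] = None
    pfs_family: Optional[str] = None
    dwell_hazard_multiplier: float = 1.0
    subsequent_lines_active: bool = True


def apply_scenario(params: ParameterSet, scenario: DSAScenario) -> tuple[ParameterSet, dict]:
    """Return (modified parameter set, run keyword arguments)."""
    settings = params.settings
    for name, value in scenario.settings.items():
        if not hasattr(settings, name):
            raise ScenarioError(f"unknown settings parameter {name!r}")
        settings = replace(settings, **{name: value})
    ps = replace(params, settings=settings)

    if scenario.hr_point is not None:
        hr = params.hr
        hr = replace(
            hr,
            point=scenario.hr_point,
            ci_low=min(hr.ci_low, scenario.hr_point),
            ci_high=max(hr.ci_high, scenario.hr_point),
        )
        ps = replace(ps, hr=hr)

    if scenario.ibrutinib_price_multiplier is not None:
        prices = dict(ps.prices.prices)
        p = prices[ARM_IBRUTINIB]
        prices[ARM_IBRUTINIB] = DrugPrice(
            p.unit_mg, p.unit_cost_eur * scenario.ibrutinib_price_multiplier
        )
        ps = replace(ps, prices=DrugPriceTable(prices=prices))

    run_kwargs: dict = {
        "subsequent_lines_active": scenario.subsequent_lines_active,
    }
    if scenario.dwell_hazard_multiplier != 1.0:
        run_kwargs["dwell_hazard_multiplier"] = scenario.dwell_hazard_multiplier
    if scenario.pfs_family is not None:
        if scenario.pfs_family == "loglogistic":
            run_kwargs["pfs_curve"] = match_loglogistic(ps.pfs_ibrutinib)
        elif scenario.pfs_family == "weibull":
            pass
        else:
            raise ScenarioError(f"unknown projection family {scenario.pfs_family!r}")
    return ps, run_kwargs


def table_scenarios() -> list[DSAScenario]:
    """The built-in one-way scenario set of the published analysis."""
    inv = 1.0
    return [
        DSAScenario("horizon_10y", "Time horizon 10 years",
                    settings={"horizon_years": 10.0}),
        DSAScenario("horizon_20y", "Time horizon 20 years",
                    settings={"horizon_years": 20.0}),
        DSAScenario("effects_discount_0", "Health discount 0.0%",
                    settings={"discount_rate_effects": 0.0}),
        DSAScenario("costs_discount_0", "Cost discount 0.0%",
                    settings={"discount_rate_costs": 0.0}),
        DSAScenario("loglogistic_projection", "PFS projection: log-logistic",
                    pfs_family="loglogistic"),
        DSAScenario("hr_0.22", "Hazard ratio for PFS 0.22", hr_point=0.22),
        DSAScenario("hr_0.19", "Hazard ratio for PFS 0.19", hr_point=0.19),
        DSAScenario("subsequent_lines_0", "Lines of subsequent treatment: 0",
                    subsequent_lines_active=False),
        DSAScenario("postprog_efficacy_-20", "Post-progression efficacy -20%",
                    dwell_hazard_multiplier=1.0 / 0.8),
        DSAScenario("postprog_efficacy_+20", "Post-progression efficacy +20%",
                    dwell_hazard_multiplier=1.0 / 1.2),
        DSAScenario("ibrutinib_price_-20", "Ibrutinib drug cost -20%",
                    ibrutinib_price_multiplier=0.8),
        DSAScenario("ibrutinib_price_+20", "Ibrutinib drug cost +20%",
                    ibrutinib_price_multiplier=1.2),
    ]


def run_scenario(params: ParameterSet, scenario: DSAScenario) -> CEAResult:
    ps, run_kwargs = apply_scenario(params, scenario)
    return run_base_case(ps, **run_kwargs)


def run_dsa(
    params: ParameterSet, scenarios: Sequence[DSAScenario] | None = None
) -> pd.DataFrame:
    """One row per scenario with ICER and percent change vs. base.

    The percent change is computed from unrounded ICERs.
    """
    if scenarios is None:
        scenarios = table_scenarios()
    base = run_base_case(params)
    rows = [_dsa_row("base_case", "Base case", base, base)]
    for sc in scenarios:
        rows.append(_dsa_row(sc.scenario_id, sc.description, run_scenario(params, sc), base))
    return pd.DataFrame(rows)


def _dsa_row(scenario_id: str, description: str, res: CEAResult, base: CEAResult) -> dict:
    icer = res.icer
    base_icer = base.icer
    pct = (
        (icer / base_icer - 1.0) * 100.0
        if icer is not None and base_icer not in (None, 0)
        else np.nan
    )
    return {
        "scenario": scenario_id,
        "description": description,
        "cost_ibrutinib": res.arm_a.costs.total,
        "cost_ctp": res.arm_b.costs.total,
        "delta_cost": res.delta_cost,
        "ly_ibrutinib": res.arm_a.life_years.discounted_ly,
        "ly_ctp": res.arm_b.life_years.discounted_ly,
        "delta_ly": res.delta_ly,
        "icer": icer,
        "pct_vs_base": pct,
    }


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASpec:
    """Sampling specification for the PSA.

    * hazard ratio: lognormal; ``hr_log_sd`` of ``None`` matches the
      printed 95% CI (sd = (ln hi - ln lo) / (2 * 1.96)).
    * monitoring bundles / cost scales: gamma, SE = ``cost_cv`` x mean.
    * SAE per-cycle incidences: beta by method of moments,
      SE = ``rate_cv`` x mean.
    * survival shape/scale and dwell hazards: lognormal with
      ``survival_log_sd`` on the log scale.

    Setting every hyperparameter to zero makes all draws degenerate at
    the base values.
    """

    n_samples: int = 1000
    seed: int = 0
    hr_log_sd: Optional[float] = None
    cost_cv: float = 0.2
    rate_cv: float = 0.2
    survival_log_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("cost_cv", "rate_cv", "survival_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hr_log_sd is not None and self.hr_log_sd < 0:
            raise ValueError("hr_log_sd must be >= 0")

    def metadata(self) -> dict:
        """Distribution choices, for inclusion in PSA output files."""
        return {
            "hazard_ratio": "lognormal matched to 95% CI"
            if self.hr_log_sd is None
            else f"lognormal, log-sd {self.hr_log_sd}",
            "cost_bundles": f"gamma, SE = {self.cost_cv:.0%} of mean",
            "sae_incidences": f"beta (method of moments), SE = {self.rate_cv:.0%} of mean",
            "survival_parameters": f"lognormal, log-sd {self.survival_log_sd}",
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def hr_log_sd_from_ci(hr) -> float:
    z = stats.norm.ppf(0.975)
    return float((np.log(hr.ci_high) - np.log(hr.ci_low)) / (2.0 * z))


def _lognormal(rng: np.random.Generator, point: float, log_sd: float) -> float:
    if log_sd == 0.0 or point == 0.0:
        return point
    return float(np.exp(rng.normal(np.log(point), log_sd)))


def _gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0 or mean == 0.0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _beta_mom(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0 or mean == 0.0:
        return mean
    var = (cv * mean) ** 2
    if var >= mean * (1.0 - mean):  # moments infeasible; fall back to gamma-in-[0,1]
        return min(_gamma(rng, mean, cv), 1.0)
    common = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * common, (1.0 - mean) * common))


def sample_psa(params: ParameterSet, spec: PSASpec) -> Iterator[ParameterSet]:
    """Reproducible stream of ``n_samples`` sampled parameter sets."""
    rng = np.random.default_rng(spec.seed)
    hr_sd = spec.hr_log_sd if spec.hr_log_sd is not None else hr_log_sd_from_ci(params.hr)
    for _ in range(spec.n_samples):
        hr_point = _lognormal(rng, params.hr.point, hr_sd)
        hr = replace(
            params.hr,
            point=hr_point,
            ci_low=min(params.hr.ci_low, hr_point),
            ci_high=max(params.hr.ci_high, hr_point),
        )
        curve = SurvivalCurve(
            family=params.pfs_ibrutinib.family,
            shape=_lognormal(rng, params.pfs_ibrutinib.shape, spec.survival_log_sd),
            scale=_lognormal(rng, params.pfs_ibrutinib.scale, spec.survival_log_sd),
        )
        dwell = PostProgressionDwell(
            sub1_hazard_per_year=_lognormal(
                rng, params.post_progression_dwell.sub1_hazard_per_year, spec.survival_log_sd
            ),
            sub2_hazard_per_year=_lognormal(
                rng, params.post_progression_dwell.sub2_hazard_per_year, spec.survival_log_sd
            ),
        )
        excess = ExcessMortality(
            ctp_pre_progression_per_year=_lognormal(
                rng, params.excess_mortality.ctp_pre_progression_per_year,
                spec.survival_log_sd,
            ),
            bsc_per_year=_lognormal(
                rng, params.excess_mortality.bsc_per_year, spec.survival_log_sd
            ),
        )
        sae = {
            arm: {item: _beta_mom(rng, r, spec.rate_cv) for item, r in rates.items()}
            for arm, rates in params.sae_rates.items()
        }
        mon = MonitoringCosts(
            **{
                f.name: _gamma(rng, getattr(params.monitoring_costs, f.name), spec.cost_cv)
                for f in dataclasses.fields(MonitoringCosts)
            }
        )
        scales = CostScales(
            **{
                f.name: _gamma(rng, getattr(params.cost_scales, f.name), spec.cost_cv)
                for f in dataclasses.fields(CostScales)
            }
        )
        draw = replace(
            params,
            hr=hr,
            pfs_ibrutinib=curve,
            post_progression_dwell=dwell,
            excess_mortality=excess,
            sae_rates=sae,
            monitoring_costs=mon,
            cost_scales=scales,
        )
        draw.validate()
        yield draw


def run_psa(params: ParameterSet, spec: PSASpec) -> np.ndarray:
    """Incremental (delta_cost, delta_ly) pairs, one per draw."""
    pairs = np.empty((spec.n_samples, 2))
    for i, draw in enumerate(sample_psa(params, spec)):
        try:
            res = run_base_case(draw)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"PSA draw {i} failed") from exc
        pairs[i] = (res.delta_cost, res.delta_ly)
    return pairs


@dataclass(frozen=True)
class CEACPoint:
    threshold: float
    probability_cost_effective: float


def ceac(pairs: np.ndarray, thresholds: Sequence[float]) -> list[CEACPoint]:
    """P(cost-effective) = fraction of draws with positive net monetary benefit."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("no PSA pairs supplied")
    out = []
    for lam in thresholds:
        nmb = lam * pairs[:, 1] - pairs[:, 0]
        out.append(CEACPoint(float(lam), float(np.mean(nmb > 0.0))))
    return out
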