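"""Model inputs: domain types, bundle I/O and validation.

The model is parameterised from two kinds of inputs:

* **Published tables** — the treatment-pathway mix of the current
  therapeutic pathway (CTP) arm, ex-factory drug unit prices, DRG
  inpatient tariffs for severe adverse events (SAEs) and outpatient
  tariffs.  These ship with the package and are validated against the
  printed values on load.
* **Calibrated / synthetic quantities** — progression-free survival
  (PFS) curve parameters, subsequent-line dwell hazards, excess
  mortality, SAE incidences, monitoring bundles and cost scales, which
  are not published and are reconstructed by :mod:`wmcea.calibration`
  so that model aggregates match the published result tables.

A parameter bundle is a directory of plain CSV/JSON files::

    settings.json  mix.csv  drug_prices.csv  tariffs.csv
    regimens.json  mortality_synthetic.csv  calibrated.json
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .survival import MortalityTable, SurvivalCurve

ARM_IBRUTINIB = "ibrutinib"
ARM_CTP = "ctp"
ARMS = (ARM_IBRUTINIB, ARM_CTP)

#: Fraction of progressing patients who receive an active subsequent
#: regimen; the remainder transit directly to best supportive care.
POST_PROGRESSION_ACTIVE_SHARE = 0.70

DOSE_BASES = ("flat_mg", "mg_per_m2", "mg_per_kg", "mg_per_day")


class ParameterLoadError(IOError):
    """A bundle file is missing or unreadable."""


class ParameterValidationError(ValueError):
    """A parameter value violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSettings:
    """Global run settings (time horizon, cycles, discounting, threshold)."""

    horizon_years: float = 15.0
    cycles_per_year: int = 13
    discount_rate_effects: float = 0.03
    discount_rate_costs: float = 0.03
    wtp_threshold: float = 60_000.0
    start_age: float = 65.0

    @property
    def cycle_length_years(self) -> float:
        return 1.0 / self.cycles_per_year

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))

    def validate(self) -> None:
        if not self.horizon_years > 0:
            raise ParameterValidationError("horizon_years must be > 0")
        if self.cycles_per_year < 1:
            raise ParameterValidationError("cycles_per_year must be >= 1")
        for name in ("discount_rate_effects", "discount_rate_costs"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ParameterValidationError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for body-size based dosing."""

    weight_kg: float = 75.0
    body_surface_area_m2: float = 1.8

    def validate(self) -> None:
        if self.weight_kg <= 0:
            raise ParameterValidationError("weight_kg must be > 0")
        if self.body_surface_area_m2 <= 0:
            raise ParameterValidationError("body_surface_area_m2 must be > 0")


@dataclass(frozen=True)
class MixRow:
    regimen_id: str
    pre_progression_share: float
    post_progression_share: float


@dataclass(frozen=True)
class TreatmentMix:
    """Regimen mix of the CTP arm, pre and post progression.

    Shares are fractions.  Pre-progression shares sum to 1; the
    post-progression column sums to :data:`POST_PROGRESSION_ACTIVE_SHARE`
    (the remaining patients receive best supportive care only).
    """

    rows: tuple[MixRow, ...]

    @property
    def pre_shares(self) -> dict[str, float]:
        return {r.regimen_id: r.pre_progression_share for r in self.rows}

    @property
    def post_shares(self) -> dict[str, float]:
        return {r.regimen_id: r.post_progression_share for r in self.rows}

    def post_shares_normalized(self) -> dict[str, float]:
        """Within-state regimen weights among actively treated progressors."""
        total = sum(r.post_progression_share for r in self.rows)
        if total <= 0:
            return {r.regimen_id: 0.0 for r in self.rows}
        return {r.regimen_id: r.post_progression_share / total for r in self.rows}


def validate_mix(mix: TreatmentMix, tol: float = 1e-9) -> list[str]:
    """Check the mix column totals; returns findings instead of raising."""
    findings: list[str] = []
    if not mix.rows:
        raise ParameterValidationError("treatment mix is empty")
    pre = sum(r.pre_progression_share for r in mix.rows)
    post = sum(r.post_progression_share for r in mix.rows)
    if abs(pre - 1.0) > tol:
        findings.append(f"pre-progression sum {pre:.2f} != 1.00")
    if abs(post - POST_PROGRESSION_ACTIVE_SHARE) > tol:
        findings.append(
            f"post-progression sum {post:.2f} != {POST_PROGRESSION_ACTIVE_SHARE:.2f}"
        )
    for r in mix.rows:
        if r.pre_progression_share < 0 or r.post_progression_share < 0:
            findings.append(f"negative share for {r.regimen_id}")
    return findings


@dataclass(frozen=True)
class DrugPrice:
    unit_mg: float
    unit_cost_eur: float


@dataclass(frozen=True)
class DrugPriceTable:
    """Ex-factory unit prices: drug -> (vial/capsule size in mg, EUR)."""

    prices: dict[str, DrugPrice]

    def __getitem__(self, drug: str) -> DrugPrice:
        return self.prices[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.prices

    def validate(self) -> None:
        for drug, p in self.prices.items():
            if p.unit_cost_eur <= 0 or p.unit_mg <= 0:
                raise ParameterValidationError(f"non-positive price entry for {drug}")


@dataclass(frozen=True)
class Tariff:
    code: str
    tariff_eur: float
    category: str  # "sae" (DRG inpatient) or "outpatient"


@dataclass(frozen=True)
class TariffTable:
    """National tariffs: DRG inpatient SAE tariffs + outpatient items."""

    tariffs: dict[str, Tariff]

    def __getitem__(self, item: str) -> Tariff:
        return self.tariffs[item]

    def __contains__(self, item: str) -> bool:
        return item in self.tariffs

    def sae_items(self) -> dict[str, float]:
        return {k: t.tariff_eur for k, t in self.tariffs.items() if t.category == "sae"}

    def validate(self) -> None:
        for item, t in self.tariffs.items():
            if t.tariff_eur <= 0:
                raise ParameterValidationError(f"non-positive tariff for {item}")


@dataclass(frozen=True)
class RegimenComponent:
    drug: str
    dose_basis: str
    dose_value: float
    administrations_per_cycle: int
    iv_administration: bool


@dataclass(frozen=True)
class Regimen:
    """One treatment schedule on the 4-week model cycle.

    ``max_treatment_cycles`` of ``None`` means treatment continues until
    progression (the ibrutinib convention); a finite value is a fixed
    course whose aggregate cost effect is absorbed by the calibrated
    cost scales.
    """

    regimen_id: str
    components: tuple[RegimenComponent, ...]
    iv_days_per_cycle: int = 0
    max_treatment_cycles: Optional[int] = None

    def validate(self, prices: DrugPriceTable) -> None:
        for c in self.components:
            if c.drug not in prices:
                raise ParameterValidationError(
                    f"regimen {self.regimen_id}: drug {c.drug!r} not in price table"
                )
            if c.dose_basis not in DOSE_BASES:
                raise ParameterValidationError(
                    f"regimen {self.regimen_id}: unknown dose basis {c.dose_basis!r}"
                )


@dataclass(frozen=True)
class HazardRatio:
    """PFS hazard ratio, ibrutinib vs. CTP, with its 95% CI."""

    point: float = 0.25
    ci_low: float = 0.11
    ci_high: float = 0.57

    def validate(self) -> None:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ParameterValidationError("HR must satisfy 0 < ci_low <= point <= ci_high")


@dataclass(frozen=True)
class PostProgressionDwell:
    """Per-line exit hazards (1/years) of the subsequent-treatment states."""

    sub1_hazard_per_year: float
    sub2_hazard_per_year: float

    def validate(self) -> None:
        if self.sub1_hazard_per_year <= 0 or self.sub2_hazard_per_year <= 0:
            raise ParameterValidationError("post-progression hazards must be > 0")


@dataclass(frozen=True)
class ExcessMortality:
    """Disease-attributable mortality hazards (1/years) on top of the life table."""

    ctp_pre_progression_per_year: float
    bsc_per_year: float

    def validate(self) -> None:
        if self.ctp_pre_progression_per_year < 0 or self.bsc_per_year < 0:
            raise ParameterValidationError("excess mortality hazards must be >= 0")


@dataclass(frozen=True)
class MonitoringCosts:
    """Per-cycle monitoring bundles (EUR) by state group.

    Built from the outpatient tariff items (visits, blood counts,
    immunoglobulin, ...); item frequencies are not published so the
    bundle totals are calibration outputs.
    """

    pre_progression_ibrutinib: float
    pre_progression_ctp: float
    subsequent: float
    bsc: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterValidationError(f"monitoring cost {f.name} must be >= 0")


@dataclass(frozen=True)
class CostScales:
    """Multipliers absorbing unpublished schedule/duration/dose-intensity detail.

    ``ibrutinib_dose_intensity`` is the mean relative dose intensity of
    continuous ibrutinib dosing (dose holds and reductions).
    """

    ctp_drug: float = 1.0
    ctp_admin: float = 1.0
    post_progression_regimen: float = 1.0
    ibrutinib_dose_intensity: float = 1.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterValidationError(f"cost scale {f.name} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """The complete model input bundle."""

    settings: ModelSettings
    patient: PatientProfile
    mix: TreatmentMix
    prices: DrugPriceTable
    tariffs: TariffTable
    regimens: tuple[Regimen, ...]
    hr: HazardRatio
    pfs_ibrutinib: SurvivalCurve
    post_progression_dwell: PostProgressionDwell
    excess_mortality: ExcessMortality
    sae_rates: dict[str, dict[str, float]]  # arm -> SAE item -> per-cycle incidence
    background_mortality: MortalityTable
    monitoring_costs: MonitoringCosts
    cost_scales: CostScales

    def regimen(self, regimen_id: str) -> Regimen:
        for r in self.regimens:
            if r.regimen_id == regimen_id:
                return r
        raise KeyError(regimen_id)

    def validate(self) -> None:
        self.settings.validate()
        self.patient.validate()
        findings = validate_mix(self.mix)
        if findings:
            raise ParameterValidationError("treatment mix: " + "; ".join(findings))
        self.prices.validate()
        self.tariffs.validate()
        for r in self.regimens:
            r.validate(self.prices)
        mix_ids = set(self.mix.pre_shares)
        reg_ids = {r.regimen_id for r in self.regimens}
        missing = mix_ids - reg_ids
        if missing:
            raise ParameterValidationError(f"mix regimens without schedule: {sorted(missing)}")
        self.hr.validate()
        self.post_progression_dwell.validate()
        self.excess_mortality.validate()
        sae_items = self.tariffs.sae_items()
        for arm in ARMS:
            if arm not in self.sae_rates:
                raise ParameterValidationError(f"sae_rates missing arm {arm!r}")
            for item, rate in self.sae_rates[arm].items():
                if item not in sae_items:
                    raise ParameterValidationError(f"SAE rate for untariffed event {item!r}")
                if not (0.0 <= rate <= 1.0):
                    raise ParameterValidationError(f"SAE rate for {item!r} outside [0, 1]")
        self.monitoring_costs.validate()
        self.cost_scales.validate()
        ib = self.regimen(ARM_IBRUTINIB)
        if ib.iv_days_per_cycle != 0 or any(c.iv_administration for c in ib.components):
            raise ParameterValidationError("ibrutinib regimen must be oral")
        if ib.max_treatment_cycles is not None:
            raise ParameterValidationError("ibrutinib continues until progression")


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_MORTALITY_FILES = ("mortality_synthetic.csv", "mortality.csv")


def _require(path: Path) -> Path:
    if not path.exists():
        raise ParameterLoadError(f"missing bundle file: {path}")
    return path


def default_bundle_path() -> Path:
    """Directory of the parameter bundle shipped with the package."""
    return Path(resources.files("wmcea") / "data")  # type: ignore[arg-type]


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a parameter bundle from a directory."""
    path = Path(path)
    if not path.is_dir():
        raise ParameterLoadError(f"bundle directory not found: {path}")

    with open(_require(path / "settings.json")) as fh:
        s = json.load(fh)
    patient = PatientProfile(**s.pop("patient", {}))
    settings = ModelSettings(**s)

    mix_df = pd.read_csv(_require(path / "mix.csv"))
    mix = TreatmentMix(
        rows=tuple(
            MixRow(str(r.regimen_id), float(r.pre_pct) / 100.0, float(r.post_pct) / 100.0)
            for r in mix_df.itertuples()
        )
    )

    price_df = pd.read_csv(_require(path / "drug_prices.csv"))
    prices = DrugPriceTable(
        prices={
            str(r.drug): DrugPrice(float(r.unit_mg), float(r.unit_cost_eur))
            for r in price_df.itertuples()
        }
    )

    tariff_df = pd.read_csv(_require(path / "tariffs.csv"), dtype={"code": str})
    tariffs = TariffTable(
        tariffs={
            str(r.item): Tariff(
                "" if pd.isna(r.code) else str(r.code), float(r.tariff_eur), str(r.category)
            )
            for r in tariff_df.itertuples()
        }
    )

    with open(_require(path / "regimens.json")) as fh:
        reg_doc = json.load(fh)
    regimens = tuple(
        Regimen(
            regimen_id=r["regimen_id"],
            components=tuple(RegimenComponent(**c) for c in r["components"]),
            iv_days_per_cycle=int(r.get("iv_days_per_cycle", 0)),
            max_treatment_cycles=r.get("max_treatment_cycles"),
        )
        for r in reg_doc["regimens"]
    )

    mort_path = next((path / f for f in _MORTALITY_FILES if (path / f).exists()), None)
    if mort_path is None:
        raise ParameterLoadError(f"missing bundle file: {path / _MORTALITY_FILES[0]}")
    background = MortalityTable.from_csv(mort_path)

    with open(_require(path / "calibrated.json")) as fh:
        cal = json.load(fh)
    pfs = SurvivalCurve(**cal["pfs_ibrutinib"])
    dwell = PostProgressionDwell(**cal["post_progression_dwell"])
    excess = ExcessMortality(**cal["excess_mortality"])
    hr = HazardRatio(**cal.get("hazard_ratio", {}))
    monitoring = MonitoringCosts(**cal["monitoring_costs"])
    scales = CostScales(**cal["cost_scales"])
    sae_rates = {arm: dict(rates) for arm, rates in cal["sae_rates"].items()}

    ps = ParameterSet(
        settings=settings,
        patient=patient,
        mix=mix,
        prices=prices,
        tariffs=tariffs,
        regimens=regimens,
        hr=hr,
        pfs_ibrutinib=pfs,
        post_progression_dwell=dwell,
        excess_mortality=excess,
        sae_rates=sae_rates,
        background_mortality=background,
        monitoring_costs=monitoring,
        cost_scales=scales,
    )
    ps.validate()
    return ps


def calibrated_to_dict(ps: ParameterSet) -> dict:
    """The calibrated/synthetic half of a ParameterSet as a JSON document."""
    return {
        "pfs_ibrutinib": dataclasses.asdict(ps.pfs_ibrutinib),
        "post_progression_dwell": dataclasses.asdict(ps.post_progression_dwell),
        "excess_mortality": dataclasses.asdict(ps.excess_mortality),
        "hazard_ratio": dataclasses.asdict(ps.hr),
        "monitoring_costs": dataclasses.asdict(ps.monitoring_costs),
        "cost_scales": dataclasses.asdict(ps.cost_scales),
        "sae_rates": {arm: dict(rates) for arm, rates in ps.sae_rates.items()},
    }


def write_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    """Write a bundle directory; ``load_parameter_set`` round-trips it exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    settings = dataclasses.asdict(ps.settings)
    settings["patient"] = dataclasses.asdict(ps.patient)
    with open(path / "settings.json", "w") as fh:
        json.dump(settings, fh, indent=2)

    with open(path / "mix.csv", "w") as fh:
        fh.write("regimen_id,pre_pct,post_pct\n")
        for r in ps.mix.rows:
            fh.write(
                f"{r.regimen_id},{_fmt(r.pre_progression_share * 100)},"
                f"{_fmt(r.post_progression_share * 100)}\n"
            )

    with open(path / "drug_prices.csv", "w") as fh:
        fh.write("drug,unit_mg,unit_cost_eur\n")
        for drug, p in ps.prices.prices.items():
            fh.write(f"{drug},{_fmt(p.unit_mg)},{_fmt(p.unit_cost_eur)}\n")

    with open(path / "tariffs.csv", "w") as fh:
        fh.write("item,code,tariff_eur,category\n")
        for item, t in ps.tariffs.tariffs.items():
            fh.write(f"{item},{t.code},{_fmt(t.tariff_eur)},{t.category}\n")

    reg_doc = {
        "regimens": [
            {
                "regimen_id": r.regimen_id,
                "components": [dataclasses.asdict(c) for c in r.components],
                "iv_days_per_cycle": r.iv_days_per_cycle,
                "max_treatment_cycles": r.max_treatment_cycles,
            }
            for r in ps.regimens
        ]
    }
    with open(path / "regimens.json", "w") as fh:
        json.dump(reg_doc, fh, indent=2)

    ps.background_mortality.to_csv(path / "mortality_synthetic.csv")

    with open(path / "calibrated.json", "w") as fh:
        json.dump(calibrated_to_dict(ps), fh, indent=2)


def _fmt(x: float) -> str:
    """Render a float without losing precision, dropping a trailing '.0'."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def load_default_parameters() -> ParameterSet:
    """The shipped bundle: printed tables plus the shipped calibration."""
    return load_parameter_set(default_bundle_path())


def load_default_targets() -> dict:
    """The published aggregates used as calibration targets."""
    with open(default_bundle_path() / "targets.json") as fh:
        return json.load(fh)
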