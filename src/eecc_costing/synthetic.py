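"""Synthetic cost-model inputs and the packaged category-level reference model.

Two granularities are shipped:

* :func:`generate_model` draws a full item-level model — resource lines,
  price book, salary schedule and oxygen scenarios — with the statistical
  structure the analysis assumes: moderate patients consume
  identification-stream resources only, diagnostics exist only in advanced
  care, prices are lognormal around country-profile anchors, and staff are
  more expensive in the Kenya-like profile than the Tanzania-like one.  The
  generator keeps independent bookkeeping of the daily cost it intends each
  category to have, so pipeline output can be checked against it.

* :func:`reference_fixture` loads the packaged category-level model whose
  valued category costs equal the published-style reference tables for
  Tanzania and Kenya (both care levels, all severities), together with the
  back-derived staffing scenario bounds, length-of-stay table and oxygen
  calibration.  It exists because the underlying item-level price lists are
  not public, while the category-level outputs are.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .aggregation import CostBreakdown
from .ingredients import (
    CareLevel,
    CareStream,
    CostCategory,
    CostType,
    Country,
    Currency,
    Money,
    ResourceLine,
    Severity,
    StaffCadre,
    UnitPrice,
    write_pricebook,
    write_resource_table,
    write_salary_schedule,
)
from .oxygen import OxygenMode, OxygenScenario, OxygenUseProfile, cost_per_litre
from .scenarios import ScenarioSpec
from .valuation import CostingContext, annuity_factor
from .admissions import LosTable, MixWeights, default_los_table

_M, _S, _C = Severity.MODERATE, Severity.SEVERE, Severity.CRITICAL
_BOTH = frozenset({CareLevel.EECC, CareLevel.ACC})
_ACC_ONLY = frozenset({CareLevel.ACC})

#: Annual salary anchors in USD by cadre; the KE-like profile is uniformly
#: above the TZ-like one (staff time is more expensive in Kenya).
SALARY_ANCHORS: dict[str, dict[str, float]] = {
    "TZ": {"assistant": 3000.0, "nurse": 4500.0, "doctor": 9000.0, "consultant": 18000.0},
    "KE": {"assistant": 7500.0, "nurse": 11250.0, "doctor": 22500.0, "consultant": 45000.0},
}

#: Reference oxygen demand: severe patients on 5 L/min for 24 h/day.
SEVERE_FLOW_L_PER_MIN = 5.0
SEVERE_HOURS_PER_DAY = 24.0
#: Daily oxygen cost (USD) the district concentrator scenario is calibrated to.
SEVERE_OXYGEN_USD_PER_DAY = 4.74
CRITICAL_OXYGEN_USD_PER_DAY = 19.67
ACC_CRITICAL_OXYGEN_USD_PER_DAY = 36.17


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic item-level generator."""

    seed: int = 0
    country_profile: str = "TZ"  # "TZ" or "KE"
    n_items_per_category: int = 2
    price_dispersion: float = 0.3  # lognormal sigma on goods prices
    salary_grade_spread: float = 0.2  # lognormal sigma on salaries

    def __post_init__(self) -> None:
        if self.country_profile not in SALARY_ANCHORS:
            raise ValueError("country_profile must be 'TZ' or 'KE'")
        if self.n_items_per_category < 1:
            raise ValueError("n_items_per_category must be >= 1")
        if self.price_dispersion <= 0 or self.salary_grade_spread <= 0:
            raise ValueError("dispersion parameters must be positive")


@dataclass
class GeneratedModel:
    """A generated model plus the generator's own expected-cost bookkeeping."""

    config: GeneratorConfig
    lines: list[ResourceLine]
    prices: dict[str, UnitPrice]
    salaries: list[StaffCadre]
    oxygen_scenarios: dict[OxygenMode, OxygenScenario]
    #: (care_level, severity, category) -> intended USD per patient-day,
    #: computed with arithmetic independent of the valuation module.
    expected_category_costs: dict[tuple[CareLevel, Severity, CostCategory], float]

    @property
    def country(self) -> Country:
        return Country(self.config.country_profile)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "resources": outdir / "resources.csv",
            "pricebook": outdir / "pricebook.csv",
            "salaries": outdir / "salaries.csv",
        }
        write_resource_table(self.lines, paths["resources"])
        write_pricebook(self.prices, paths["pricebook"])
        write_salary_schedule(self.salaries, paths["salaries"])
        return paths


def _bounded_lognormal(rng: np.random.Generator, sigma: float) -> float:
    """Multiplicative lognormal noise with z clipped to +/-2 (keeps country
    salary orderings strict)."""
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    return float(np.exp(sigma * z))


def generate_model(cfg: GeneratorConfig, ctx: CostingContext | None = None) -> GeneratedModel:
    """Generate a consistent item-level cost model.

    The output always passes :func:`eecc_costing.ingredients.validate_model`
    with an empty report and obeys the structural rules of the costing:
    treatment-stream lines have zero moderate quantity, diagnostics lines are
    advanced-care only, and oxygen never contributes to moderate essential
    care.
    """
    ctx = ctx or CostingContext()
    rng = np.random.default_rng(cfg.seed)
    profile = cfg.country_profile
    currency = Currency.TZS if profile == "TZ" else Currency.KES
    fx = ctx.fx_rate_tzs_per_usd if profile == "TZ" else ctx.fx_rate_kes_per_usd
    uplift = 1.0 + ctx.transport_uplift

    lines: list[ResourceLine] = []
    prices: dict[str, UnitPrice] = {}
    expected: dict[tuple[CareLevel, Severity, CostCategory], float] = {
        (lvl, sev, cat): 0.0
        for lvl in CareLevel
        for sev in Severity
        for cat in CostCategory
    }

    def book(line: ResourceLine, daily_usd: dict[Severity, float]) -> None:
        # Independent bookkeeping: ACC totals include every line, EECC totals
        # only lines applicable to the essential package.
        for sev, usd in daily_usd.items():
            expected[(CareLevel.ACC, sev, line.category)] += usd
            if CareLevel.EECC in line.applicability:
                expected[(CareLevel.EECC, sev, line.category)] += usd

    def add_recurrent(
        item_id: str,
        name: str,
        category: CostCategory,
        stream: CareStream,
        applicability: frozenset[CareLevel],
        qty: dict[Severity, float],
        price_usd_anchor: float,
        needs_uplift: bool,
        unit: str,
        local_currency: bool = True,
    ) -> None:
        price_usd = price_usd_anchor * _bounded_lognormal(rng, cfg.price_dispersion)
        amount = round(price_usd * fx if local_currency else price_usd, 6)
        cur = currency if local_currency else Currency.USD
        prices[item_id] = UnitPrice(
            item_id=item_id,
            price=Money(amount, cur),
            cost_type=CostType.RECURRENT,
            needs_uplift=needs_uplift,
            source="synthetic",
        )
        line = ResourceLine(item_id, name, category, stream, applicability, qty, unit)
        lines.append(line)
        eff = (amount / fx if local_currency else amount) * (uplift if needs_uplift else 1.0)
        book(line, {sev: q * eff for sev, q in qty.items()})

    def add_capital(
        item_id: str,
        name: str,
        category: CostCategory,
        stream: CareStream,
        applicability: frozenset[CareLevel],
        qty: dict[Severity, float],
        price_usd_anchor: float,
        life_years: float,
        needs_uplift: bool,
    ) -> None:
        price_usd = price_usd_anchor * _bounded_lognormal(rng, cfg.price_dispersion)
        prices[item_id] = UnitPrice(
            item_id=item_id,
            price=Money(round(price_usd, 6), Currency.USD),
            cost_type=CostType.CAPITAL,
            useful_life_years=life_years,
            needs_uplift=needs_uplift,
            source="synthetic",
        )
        line = ResourceLine(
            item_id, name, category, stream, applicability, qty, "device-fraction"
        )
        lines.append(line)
        af = (1.0 - (1.0 + ctx.discount_rate) ** -life_years) / ctx.discount_rate
        annual = round(price_usd, 6) * (uplift if needs_uplift else 1.0) / af
        book(line, {sev: annual / 365.0 * q for sev, q in qty.items()})

    # --- salary schedule ---------------------------------------------------
    salaries: list[StaffCadre] = []
    drawn_salaries: dict[str, float] = {}
    for cadre, anchor in SALARY_ANCHORS[profile].items():
        salary = anchor * _bounded_lognormal(rng, cfg.salary_grade_spread)
        drawn_salaries[cadre] = salary
        salaries.append(
            StaffCadre(
                cadre=cadre,
                grade="reference",
                annual_salary=Money(round(salary, 2), Currency.USD),
                country=Country(profile),
            )
        )

    def add_staff(
        item_id: str,
        name: str,
        cadre: str,
        stream: CareStream,
        applicability: frozenset[CareLevel],
        minutes: dict[Severity, float],
    ) -> None:
        salary = round(drawn_salaries[cadre], 2)
        prices[item_id] = UnitPrice(
            item_id=item_id,
            price=Money(salary, Currency.USD),
            cost_type=CostType.STAFF_TIME,
            needs_uplift=False,
            source=f"synthetic salary schedule: {cadre}",
        )
        line = ResourceLine(
            item_id, name, CostCategory.STAFFING, stream, applicability, minutes, "minutes"
        )
        lines.append(line)
        book(line, {s: salary * m / ctx.working_minutes_per_year for s, m in minutes.items()})

    # --- staffing ----------------------------------------------------------
    add_staff(
        "staff_vitals_nurse",
        "Vital-signs monitoring (nurse)",
        "nurse",
        CareStream.IDENTIFICATION,
        _BOTH,
        {_M: 20.0, _S: 45.0, _C: 60.0},
    )
    add_staff(
        "staff_review_doctor",
        "Clinical review (doctor)",
        "doctor",
        CareStream.IDENTIFICATION,
        _BOTH,
        {_M: 5.0, _S: 10.0, _C: 15.0},
    )
    add_staff(
        "staff_treatment_nurse",
        "Treatment nursing care",
        "nurse",
        CareStream.TREATMENT,
        _BOTH,
        {_M: 0.0, _S: 60.0, _C: 120.0},
    )
    add_staff(
        "staff_icu_nurse",
        "ICU nursing (advanced care)",
        "nurse",
        CareStream.TREATMENT,
        _ACC_ONLY,
        {_M: 0.0, _S: 120.0, _C: 600.0},
    )
    add_staff(
        "staff_intensivist",
        "Intensivist cover (advanced care)",
        "consultant",
        CareStream.TREATMENT,
        _ACC_ONLY,
        {_M: 0.0, _S: 30.0, _C: 120.0},
    )

    # --- hotel -------------------------------------------------------------
    add_recurrent(
        "hotel_bed_day",
        "Daily bed charge (accommodation + overheads)",
        CostCategory.HOTEL,
        CareStream.IDENTIFICATION,
        _BOTH,
        {_M: 1.0, _S: 1.0, _C: 1.0},
        price_usd_anchor=0.05,
        needs_uplift=False,
        unit="bed-day",
    )

    # --- oxygen ------------------------------------------------------------
    oxygen_scenarios = default_oxygen_scenarios(ctx)
    usd_per_litre = cost_per_litre(
        oxygen_scenarios[OxygenMode.CONCENTRATOR_WITH_CYLINDER_BACKUP], ctx
    )
    severe_litres = SEVERE_FLOW_L_PER_MIN * 60.0 * SEVERE_HOURS_PER_DAY
    critical_litres = severe_litres * (
        CRITICAL_OXYGEN_USD_PER_DAY / SEVERE_OXYGEN_USD_PER_DAY
    )
    add_recurrent(
        "oxygen_supply",
        "Oxygen therapy (delivered litres)",
        CostCategory.OXYGEN,
        CareStream.TREATMENT,
        _BOTH,
        {_M: 0.0, _S: severe_litres, _C: critical_litres},
        price_usd_anchor=usd_per_litre,
        needs_uplift=False,
        unit="litre",
        local_currency=False,
    )
    add_recurrent(
        "oxygen_high_flow_acc",
        "High-flow oxygen top-up (advanced care)",
        CostCategory.OXYGEN,
        CareStream.TREATMENT,
        _ACC_ONLY,
        {
            _M: 0.0,
            _S: 0.0,
            _C: severe_litres
            * (ACC_CRITICAL_OXYGEN_USD_PER_DAY - CRITICAL_OXYGEN_USD_PER_DAY)
            / SEVERE_OXYGEN_USD_PER_DAY,
        },
        price_usd_anchor=usd_per_litre,
        needs_uplift=False,
        unit="litre",
        local_currency=False,
    )

    # --- consumable categories ----------------------------------------------
    n = cfg.n_items_per_category
    pharma_anchor = 0.9 if profile == "TZ" else 0.3
    for i in range(n):
        add_recurrent(
            f"pharma_{i}",
            f"Essential medicine {i}",
            CostCategory.PHARMACEUTICALS,
            CareStream.TREATMENT,
            _BOTH,
            {_M: 0.0, _S: 1.0 + i, _C: 2.0 + i},
            price_usd_anchor=pharma_anchor / n,
            needs_uplift=True,
            unit="dose",
        )
        add_recurrent(
            f"pharma_acc_{i}",
            f"Advanced-care medicine {i} (sedation, vasopressors)",
            CostCategory.PHARMACEUTICALS,
            CareStream.TREATMENT,
            _ACC_ONLY,
            {_M: 0.0, _S: 0.0, _C: 4.0},
            price_usd_anchor=12.0 / n,
            needs_uplift=True,
            unit="dose",
        )
        add_recurrent(
            f"fluids_{i}",
            f"IV fluids and giving sets {i}",
            CostCategory.NONPHARMA_RECURRENT,
            CareStream.TREATMENT,
            _BOTH,
            {_M: 0.0, _S: 1.0, _C: 2.0},
            price_usd_anchor=0.5 / n,
            needs_uplift=True,
            unit="set",
        )
        add_recurrent(
            f"ppe_{i}",
            f"PPE set {i} (gloves, mask, apron)",
            CostCategory.PPE,
            CareStream.IDENTIFICATION,
            _BOTH,
            {_M: 2.0, _S: 4.0, _C: 8.0},
            price_usd_anchor=0.03 / n,
            needs_uplift=True,
            unit="set",
        )
        add_capital(
            f"equip_{i}",
            f"Monitoring equipment {i} (shared)",
            CostCategory.NONPHARMA_CAPITAL,
            CareStream.IDENTIFICATION,
            _BOTH,
            {_M: 0.05, _S: 0.2, _C: 0.3},
            price_usd_anchor=400.0 / n,
            life_years=5.0,
            needs_uplift=True,
        )
        add_recurrent(
            f"diagnostics_{i}",
            f"Support-service diagnostics {i} (advanced care)",
            CostCategory.DIAGNOSTICS,
            CareStream.TREATMENT,
            _ACC_ONLY,
            {_M: 0.0, _S: 1.0, _C: 2.0},
            price_usd_anchor=2.0 / n,
            needs_uplift=False,
            unit="test",
        )
    add_capital(
        "equip_ventilator",
        "Mechanical ventilator (advanced care)",
        CostCategory.NONPHARMA_CAPITAL,
        CareStream.TREATMENT,
        _ACC_ONLY,
        {_M: 0.0, _S: 0.1, _C: 1.0},
        price_usd_anchor=12000.0,
        life_years=8.0,
        needs_uplift=True,
    )

    return GeneratedModel(
        config=cfg,
        lines=lines,
        prices=prices,
        salaries=salaries,
        oxygen_scenarios=oxygen_scenarios,
        expected_category_costs=expected,
    )


# ---------------------------------------------------------------------------
# Oxygen scenario presets
# ---------------------------------------------------------------------------


def _calibrated_litres(
    capital: tuple[tuple[float, float], ...],
    recurrent: float,
    refill: float,
    ctx: CostingContext,
) -> float:
    """Annual litres such that the severe profile costs its reference USD/day."""
    annual = (
        sum(p / annuity_factor(ctx.discount_rate, life) for p, life in capital)
        + recurrent
        + refill
    )
    target_usd_per_litre = SEVERE_OXYGEN_USD_PER_DAY / (
        SEVERE_FLOW_L_PER_MIN * 60.0 * SEVERE_HOURS_PER_DAY
    )
    return annual / target_usd_per_litre


def default_oxygen_scenarios(
    ctx: CostingContext | None = None,
) -> dict[OxygenMode, OxygenScenario]:
    """District-hospital oxygen supply presets.

    The concentrator-with-backup scenario — the reference supply — is
    calibrated so a severe patient (5 L/min, 24 h) costs the reference
    4.74 USD/day; the cylinder-only scenario delivers the same litres at a
    higher refill spend and therefore a higher USD/L; the ICU high-flow
    scenario scales plant and litres for an advanced-care ward.
    """
    ctx = ctx or CostingContext()
    conc_capital = tuple([(1500.0, 5.0)] * 10 + [(2000.0, 10.0)])
    conc_litres = _calibrated_litres(conc_capital, 2500.0, 600.0, ctx)
    cyl_capital = ((2000.0, 10.0),)
    icu_capital = ((25000.0, 10.0),)
    icu_litres = _calibrated_litres(icu_capital, 6000.0, 2000.0, ctx)
    return {
        OxygenMode.CONCENTRATOR_WITH_CYLINDER_BACKUP: OxygenScenario(
            mode=OxygenMode.CONCENTRATOR_WITH_CYLINDER_BACKUP,
            hospital_beds=120,
            occupancy=0.8,
            capital_components=conc_capital,
            recurrent_usd_per_year=2500.0,
            annual_refill_usd=600.0,
            annual_litres_delivered=conc_litres,
        ),
        OxygenMode.CYLINDER_ONLY: OxygenScenario(
            mode=OxygenMode.CYLINDER_ONLY,
            hospital_beds=120,
            occupancy=0.8,
            capital_components=cyl_capital,
            recurrent_usd_per_year=1500.0,
            annual_refill_usd=9000.0,
            annual_litres_delivered=conc_litres,
        ),
        OxygenMode.ICU_HIGH_FLOW: OxygenScenario(
            mode=OxygenMode.ICU_HIGH_FLOW,
            hospital_beds=12,
            occupancy=0.8,
            capital_components=icu_capital,
            recurrent_usd_per_year=6000.0,
            annual_refill_usd=2000.0,
            annual_litres_delivered=icu_litres,
        ),
    }


def default_oxygen_profiles() -> dict[tuple[CareLevel, Severity], OxygenUseProfile]:
    """Flow-rate profiles per care level and severity.

    Severe: 5 L/min for 24 h.  Critical at the essential level: a high-flow
    equivalent of ~20.7 L/min, and at the advanced level a ventilator/high-
    flow preset of ~38.2 L/min; both are calibrated against the reference
    daily oxygen costs at the reference USD/L.
    """
    crit_eecc_flow = SEVERE_FLOW_L_PER_MIN * (
        CRITICAL_OXYGEN_USD_PER_DAY / SEVERE_OXYGEN_USD_PER_DAY
    )
    crit_acc_flow = SEVERE_FLOW_L_PER_MIN * (
        ACC_CRITICAL_OXYGEN_USD_PER_DAY / SEVERE_OXYGEN_USD_PER_DAY
    )
    return {
        (CareLevel.EECC, _M): OxygenUseProfile(_M, 0.0, 0.0),
        (CareLevel.EECC, _S): OxygenUseProfile(_S, SEVERE_FLOW_L_PER_MIN, 24.0),
        (CareLevel.EECC, _C): OxygenUseProfile(_C, crit_eecc_flow, 24.0),
        (CareLevel.ACC, _S): OxygenUseProfile(_S, SEVERE_FLOW_L_PER_MIN, 24.0),
        (CareLevel.ACC, _C): OxygenUseProfile(_C, crit_acc_flow, 24.0),
    }


# ---------------------------------------------------------------------------
# Packaged category-level reference model
# ---------------------------------------------------------------------------


@dataclass
class ReferenceModel:
    """Category-granular reference cost model for Tanzania and Kenya.

    Category daily costs are entered directly at the values of the reference
    breakdown tables; staffing scenario bounds are the cadre re-valuations
    back-derived from the published-style total ranges.
    """

    category_costs: dict[tuple[Country, CareLevel, Severity, CostCategory], float]
    staffing_bounds: dict[tuple[Country, CareLevel, Severity], tuple[float, float]]
    los_table: LosTable = field(default_factory=default_los_table)
    mix_weights: MixWeights = field(default_factory=MixWeights)

    def cells(self) -> list[tuple[Country, CareLevel, Severity]]:
        return sorted(
            {(c, lvl, sev) for (c, lvl, sev, _cat) in self.category_costs},
            key=lambda t: (t[0].value, t[1].value, t[2]),
        )

    def breakdown(
        self, country: Country, care_level: CareLevel, severity: Severity
    ) -> CostBreakdown:
        per_cat = {
            cat: self.category_costs.get((country, care_level, severity, cat), 0.0)
            for cat in CostCategory
        }
        if all(
            (country, care_level, severity, cat) not in self.category_costs
            for cat in CostCategory
        ):
            raise KeyError(
                f"no reference cell for {country.value}/{care_level.value}/"
                f"{severity.label}"
            )
        return CostBreakdown(
            country=country,
            severity=severity,
            care_level=care_level,
            per_category_usd=per_cat,
        )

    def line_costs(
        self, country: Country, care_level: CareLevel, severity: Severity
    ) -> list["LineDailyCost"]:
        """One valued pseudo-line per category, for the aggregation pipeline."""
        from .valuation import LineDailyCost

        return [
            LineDailyCost(
                item_id=f"ref_{cat.value}",
                category=cat,
                severity=severity,
                care_level=care_level,
                usd_per_patient_day=self.category_costs.get(
                    (country, care_level, severity, cat), 0.0
                ),
                country=country,
            )
            for cat in CostCategory
        ]

    def scenario_spec(
        self, country: Country, care_level: CareLevel, severity: Severity
    ) -> ScenarioSpec:
        """Scenario spec with the cell's staffing bounds as an override."""
        lo, hi = self.staffing_bounds[(country, care_level, severity)]
        return ScenarioSpec(
            per_category_overrides={CostCategory.STAFFING: (lo, hi)}
        )


def _data_text(name: str) -> str:
    return resources.files("eecc_costing.data").joinpath(name).read_text(
        encoding="utf-8"
    )


def reference_fixture() -> ReferenceModel:
    """Load the packaged category-level reference model."""
    costs: dict[tuple[Country, CareLevel, Severity, CostCategory], float] = {}
    for row in csv.DictReader(_data_text("reference_costs.csv").splitlines()):
        key = (
            Country(row["country"]),
            CareLevel(row["care_level"]),
            Severity.from_label(row["severity"]),
            CostCategory(row["category"]),
        )
        costs[key] = float(row["usd_per_day"])
    bounds: dict[tuple[Country, CareLevel, Severity], tuple[float, float]] = {}
    for row in csv.DictReader(
        _data_text("reference_staffing_bounds.csv").splitlines()
    ):
        key = (
            Country(row["country"]),
            CareLevel(row["care_level"]),
            Severity.from_label(row["severity"]),
        )
        bounds[key] = (float(row["low_usd"]), float(row["high_usd"]))
    return ReferenceModel(category_costs=costs, staffing_bounds=bounds)
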