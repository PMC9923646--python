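"""Scenario bounds and gamma Monte Carlo probabilistic sensitivity analysis.

Deterministic scenario analysis perturbs the categories whose assumptions
are least certain: oxygen (and, for advanced care, pharmaceutical) daily
costs move by an indicative +/-25%, and staffing is re-valued with the
cheapest cadre able to perform the tasks (low) or the highest nurse grade
plus a consultant-level doctor (high).  Every cell of the resulting grid is
a (low, reference, high) triple with low <= reference <= high.

The probabilistic analysis reads each category's (low, high) as central-95%
limits of a gamma distribution fitted by moments — mean = reference,
sd = (high - low)/3.92, shape = (mean/sd)^2, scale = sd^2/mean — samples the
categories independently, and sums draws into a total whose sample mean and
empirical 2.5/97.5 percentiles are reported.  Each category has its own
random stream derived from the root seed and a stable hash of the category
name, so adding a category never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .aggregation import CostBreakdown
from .ingredients import CareLevel, CostCategory, StaffCadre, ValidationError
from .valuation import CostingContext, convert_to_usd


@dataclass(frozen=True)
class ScenarioSpec:
    """What the scenario grid varies.

    ``per_category_overrides`` gives explicit absolute (low, high) USD bounds
    for a category and takes precedence over the multiplier rules; it is how
    category-granular models (no item detail) supply staffing re-valuations.
    """

    oxygen_multipliers: tuple[float, float] = (0.75, 1.25)
    pharma_multipliers: tuple[float, float] = (0.75, 1.25)
    staffing_mode: str = "cadre_range"  # "reference" or "cadre_range"
    per_category_overrides: dict[CostCategory, tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("oxygen_multipliers", self.oxygen_multipliers),
            ("pharma_multipliers", self.pharma_multipliers),
        ):
            if not lo <= 1.0 <= hi:
                raise ValidationError(f"{name} must satisfy low <= 1 <= high")
        if self.staffing_mode not in {"reference", "cadre_range"}:
            raise ValidationError(
                f"staffing_mode must be 'reference' or 'cadre_range', "
                f"got {self.staffing_mode!r}"
            )


@dataclass(frozen=True)
class ScenarioBounds:
    """Per-category (low, reference, high) USD/patient-day triples."""

    per_category: dict[CostCategory, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for cat, (lo, ref, hi) in self.per_category.items():
            if not (lo <= ref <= hi):
                raise ValidationError(
                    f"category {cat.value}: bounds must satisfy "
                    f"low <= reference <= high, got ({lo}, {ref}, {hi})"
                )

    @property
    def total_low(self) -> float:
        return sum(t[0] for t in self.per_category.values())

    @property
    def total_reference(self) -> float:
        return sum(t[1] for t in self.per_category.values())

    @property
    def total_high(self) -> float:
        return sum(t[2] for t in self.per_category.values())


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo summary of a daily-cost total, with provenance."""

    mean_usd: float
    ci_low_usd: float
    ci_high_usd: float
    draws: int
    seed: int


def build_bounds(
    reference: CostBreakdown,
    spec: ScenarioSpec,
    salary_schedule: list[StaffCadre] | None = None,
    staff_minutes_per_day: dict[str, float] | None = None,
    ctx: CostingContext | None = None,
) -> ScenarioBounds:
    """Build the (low, reference, high) triple for every category.

    Oxygen bounds are reference x the oxygen multipliers; pharmaceutical
    bounds likewise but only at the advanced care level.  Staffing bounds
    come from an explicit override when provided, else — when a salary
    schedule and per-cadre staff minutes are given — from re-valuing all
    staff minutes at the cheapest cadre's salary rate (low) and the most
    expensive one's (high).  Untouched categories get degenerate triples.
    """
    bounds: dict[CostCategory, tuple[float, float, float]] = {}
    for cat in CostCategory:
        ref = reference.per_category_usd.get(cat, 0.0)
        if cat in spec.per_category_overrides:
            lo, hi = spec.per_category_overrides[cat]
        elif cat == CostCategory.OXYGEN:
            lo, hi = (ref * m for m in spec.oxygen_multipliers)
        elif (
            cat == CostCategory.PHARMACEUTICALS
            and reference.care_level == CareLevel.ACC
        ):
            lo, hi = (ref * m for m in spec.pharma_multipliers)
        elif cat == CostCategory.STAFFING and spec.staffing_mode == "cadre_range":
            lo, hi = _staffing_bounds_from_schedule(
                ref, salary_schedule, staff_minutes_per_day, ctx
            )
        else:
            lo, hi = ref, ref
        bounds[cat] = (lo, ref, hi)
    return ScenarioBounds(per_category=bounds)


def _staffing_bounds_from_schedule(
    reference_usd: float,
    schedule: list[StaffCadre] | None,
    staff_minutes_per_day: dict[str, float] | None,
    ctx: CostingContext | None,
) -> tuple[float, float]:
    if not schedule or not staff_minutes_per_day:
        raise ValidationError(
            "staffing_mode 'cadre_range' needs a salary schedule and staff "
            "minutes, or an explicit staffing override"
        )
    ctx = ctx or CostingContext()
    rates = [convert_to_usd(c.annual_salary, ctx) for c in schedule]
    total_minutes = sum(staff_minutes_per_day.values())
    low = min(rates) * total_minutes / ctx.working_minutes_per_year
    high = max(rates) * total_minutes / ctx.working_minutes_per_year
    return min(low, reference_usd), max(high, reference_usd)


def fit_gamma(
    reference: float, low: float, high: float
) -> tuple[float, float] | None:
    """Method-of-moments gamma fit from scenario bounds.

    Bounds are read as central-95% limits: mean = reference,
    sd = (high - low)/3.92.  Returns (shape, scale), or ``None`` as the
    point-mass sentinel when the bounds are degenerate (sd = 0).
    """
    if not (0 <= low <= reference <= high):
        raise ValidationError(
            f"bounds must satisfy 0 <= low <= reference <= high, "
            f"got ({low}, {reference}, {high})"
        )
    sd = (high - low) / 3.92
    if sd == 0:
        return None
    if reference <= 0:
        raise ValidationError("reference must be positive for a gamma fit")
    shape = (reference / sd) ** 2
    scale = sd * sd / reference
    return shape, scale


def _category_rng(seed: int, category: CostCategory) -> np.random.Generator:
    # crc32 of the category name keeps streams stable across processes and
    # independent of dict ordering.
    entropy = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(category.value.encode())])
    return np.random.default_rng(entropy)


def sample_totals(bounds: ScenarioBounds, ctx: CostingContext) -> np.ndarray:
    """Draw ``ctx.psa_draws`` totals: independent per-category gamma samples."""
    totals = np.zeros(ctx.psa_draws)
    for cat, (lo, ref, hi) in bounds.per_category.items():
        params = fit_gamma(ref, lo, hi)
        if params is None:
            totals += ref
        else:
            shape, scale = params
            rng = _category_rng(ctx.seed, cat)
            totals += rng.gamma(shape=shape, scale=scale, size=ctx.psa_draws)
    if not np.all(np.isfinite(totals)):
        raise ValidationError("non-finite Monte Carlo sample")
    return totals


def run_psa(bounds: ScenarioBounds, ctx: CostingContext) -> PSAResult:
    """Propagate category bounds through the gamma Monte Carlo."""
    if all(lo == hi for lo, _, hi in bounds.per_category.values()):
        # fully degenerate: the point estimate, with a zero-width interval
        total = bounds.total_reference
        return PSAResult(total, total, total, ctx.psa_draws, ctx.seed)
    totals = sample_totals(bounds, ctx)
    lo_q, hi_q = ctx.ci_quantiles
    return PSAResult(
        mean_usd=float(totals.mean()),
        ci_low_usd=float(np.quantile(totals, lo_q)),
        ci_high_usd=float(np.quantile(totals, hi_q)),
        draws=ctx.psa_draws,
        seed=ctx.seed,
    )
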