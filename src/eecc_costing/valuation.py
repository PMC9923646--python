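"""Valuing resource use: currency conversion, uplift, annualization, staff time.

All raw prices are converted to USD at fixed exchange rates (defaults
2300 TZS and 115 KES per USD, the 2020 rates the cost model is calibrated
to).  Goods whose quoted price excludes shipping receive a transport and
insurance uplift (default 17.4%).  Capital purchases are spread over their
useful life as an equivalent annual cost using the annuity factor

    AF(r, L) = (1 - (1 + r)^-L) / r        (AF = L in the limit r -> 0)

with a 3% discount rate by default.  Staff time is valued from annual
public-sector salaries pro-rated by minutes of contact per patient-day.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

from .ingredients import (
    CareLevel,
    CostCategory,
    CostType,
    Country,
    Currency,
    Money,
    ResourceLine,
    Severity,
    StaffCadre,
    UnitPrice,
    ValidationError,
)

#: Days per year used to turn annualized capital costs into per-day costs.
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class CostingContext:
    """Global valuation constants.

    Defaults are the reference assumptions of the costing: 2020 exchange
    rates (1 USD = 2300 TZS = 115 KES), a 3% discount rate for capital
    annualization, a 17.4% transport/insurance uplift on shipped goods,
    1000 Monte Carlo draws and a central 95% interval for the probabilistic
    sensitivity analysis.  ``working_minutes_per_year`` (225 working days x
    8 h = 108,000 min) converts annual salaries to per-minute staff costs.
    """

    fx_rate_tzs_per_usd: float = 2300.0
    fx_rate_kes_per_usd: float = 115.0
    discount_rate: float = 0.03
    transport_uplift: float = 0.174
    working_minutes_per_year: int = 108_000
    psa_draws: int = 1000
    ci_quantiles: tuple[float, float] = (0.025, 0.975)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fx_rate_tzs_per_usd <= 0 or self.fx_rate_kes_per_usd <= 0:
            raise ValidationError("exchange rates must be strictly positive")
        if not 0 <= self.discount_rate < 1:
            raise ValidationError("discount_rate must lie in [0, 1)")
        if self.transport_uplift < 0:
            raise ValidationError("transport_uplift must be >= 0")
        if self.working_minutes_per_year <= 0:
            raise ValidationError("working_minutes_per_year must be positive")
        if self.psa_draws < 1:
            raise ValidationError("psa_draws must be >= 1")
        lo, hi = self.ci_quantiles
        if not (0 < lo < hi < 1):
            raise ValidationError("ci_quantiles must satisfy 0 < low < high < 1")


@dataclass(frozen=True)
class LineDailyCost:
    """A valued resource line: USD per patient-day for one severity and level."""

    item_id: str
    category: CostCategory
    severity: Severity
    care_level: CareLevel
    usd_per_patient_day: float
    country: Country | None = None

    def __post_init__(self) -> None:
        if self.usd_per_patient_day < 0:
            raise ValidationError(
                f"line {self.item_id!r}: USD per patient-day must be >= 0"
            )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up used for all reported values (tables at 2 dp, headlines 0 dp)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def convert_to_usd(price: Money, ctx: CostingContext) -> float:
    """Convert an amount to USD at the context's fixed exchange rates."""
    if price.currency == Currency.USD:
        return price.amount
    if price.currency == Currency.TZS:
        return price.amount / ctx.fx_rate_tzs_per_usd
    if price.currency == Currency.KES:
        return price.amount / ctx.fx_rate_kes_per_usd
    raise ValidationError(f"unknown currency {price.currency!r}")


def apply_uplift(usd_price: float, ctx: CostingContext) -> float:
    """Add the transport/insurance uplift to a USD goods price."""
    if usd_price < 0:
        raise ValidationError(f"price must be >= 0, got {usd_price}")
    return usd_price * (1.0 + ctx.transport_uplift)


def annuity_factor(discount_rate: float, useful_life_years: float) -> float:
    """Annuity factor AF = (1 - (1+r)^-L)/r; equals L in the r -> 0 limit."""
    if useful_life_years <= 0:
        raise ValidationError("useful_life_years must be positive")
    if not 0 <= discount_rate < 1:
        raise ValidationError("discount_rate must lie in [0, 1)")
    if discount_rate == 0:
        return useful_life_years
    # -expm1(-L*log1p(r)) = 1-(1+r)^-L, stable as r -> 0
    return -math.expm1(-useful_life_years * math.log1p(discount_rate)) / discount_rate


def annualize_capital(
    usd_price: float, useful_life_years: float, discount_rate: float
) -> float:
    """Equivalent annual cost of a capital purchase (USD per year)."""
    if usd_price < 0:
        raise ValidationError("capital price must be >= 0")
    return usd_price / annuity_factor(discount_rate, useful_life_years)


def staff_cost_per_patient_day(
    cadre: StaffCadre, minutes_per_day: float, ctx: CostingContext
) -> float:
    """Value staff contact time from the cadre's annual salary."""
    if minutes_per_day < 0:
        raise ValidationError("minutes_per_day must be >= 0")
    salary_usd = convert_to_usd(cadre.annual_salary, ctx)
    return salary_usd * minutes_per_day / ctx.working_minutes_per_year


def line_daily_cost(
    line: ResourceLine,
    price: UnitPrice,
    severity: Severity,
    ctx: CostingContext,
    care_level: CareLevel = CareLevel.EECC,
    country: Country | None = None,
) -> LineDailyCost:
    """USD per patient-day for one line at one severity.

    Recurrent items: quantity x (uplifted) USD unit price.  Capital items:
    annualized USD cost / 365 x device-fraction quantity.  Staff time: the
    price is an annual salary and the quantity is minutes per patient-day.
    """
    if price.item_id != line.item_id:
        raise ValidationError(
            f"price {price.item_id!r} does not match line {line.item_id!r}"
        )
    if severity not in line.quantity_per_day:
        raise ValidationError(
            f"line {line.item_id!r} has no quantity for severity {severity.label}"
        )
    qty = line.quantity_per_day[severity]
    usd = convert_to_usd(price.price, ctx)
    if price.needs_uplift:
        usd = apply_uplift(usd, ctx)
    if price.cost_type == CostType.RECURRENT:
        daily = qty * usd
    elif price.cost_type == CostType.CAPITAL:
        annual = annualize_capital(usd, price.useful_life_years, ctx.discount_rate)
        daily = annual / DAYS_PER_YEAR * qty
    elif price.cost_type == CostType.STAFF_TIME:
        daily = usd * qty / ctx.working_minutes_per_year
    else:  # pragma: no cover - closed enumeration
        raise ValidationError(f"unknown cost type {price.cost_type!r}")
    return LineDailyCost(
        item_id=line.item_id,
        category=line.category,
        severity=severity,
        care_level=care_level,
        usd_per_patient_day=daily,
        country=country,
    )


def value_lines(
    lines: list[ResourceLine],
    prices: dict[str, UnitPrice],
    severity: Severity,
    care_level: CareLevel,
    ctx: CostingContext,
    country: Country | None = None,
) -> list[LineDailyCost]:
    """Value every line applicable to ``care_level`` at one severity.

    EECC excludes ACC-only lines; ACC includes both (the advanced package is
    defined as the essential one plus extras).
    """
    out: list[LineDailyCost] = []
    for line in lines:
        if care_level == CareLevel.EECC and not line.applies_to(CareLevel.EECC):
            continue
        out.append(
            line_daily_cost(
                line, prices[line.item_id], severity, ctx, care_level, country
            )
        )
    return out
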