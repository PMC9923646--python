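"""Oxygen-delivery costing: USD per litre under supply scenarios, and per-day cost.

Oxygen is the single largest cost driver for severe and critical respiratory
illness, so it is costed through an explicit supply model rather than a flat
consumable price.  A scenario describes how a hospital sources oxygen —
concentrators with cylinder backup, cylinders only, or a high-flow ICU
supply — as annualized capital components plus recurrent running costs
(power, maintenance, logistics) plus annual cylinder-refill spend, divided
by the litres delivered per year:

    USD/L = (sum_i annualize(capital_i) + recurrent + refills) / annual_litres

The per-patient-day oxygen cost is then a flow-rate profile priced at that
rate: flow (L/min) x 60 x hours/day x USD/L.  Bed counts and occupancy enter
only through ``annual_litres_delivered``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .ingredients import Severity, ValidationError
from .valuation import CostingContext, annualize_capital


class OxygenMode(str, enum.Enum):
    CONCENTRATOR_WITH_CYLINDER_BACKUP = "concentrator_with_cylinder_backup"
    CYLINDER_ONLY = "cylinder_only"
    ICU_HIGH_FLOW = "icu_high_flow"


@dataclass(frozen=True)
class OxygenScenario:
    """One oxygen-supply configuration for a hospital.

    ``capital_components`` is a list of (USD price, useful life in years)
    pairs; ``annual_refill_usd`` is the yearly cylinder-refill spend.
    """

    mode: OxygenMode
    hospital_beds: int
    occupancy: float
    capital_components: tuple[tuple[float, float], ...]
    recurrent_usd_per_year: float
    annual_refill_usd: float
    annual_litres_delivered: float

    def __post_init__(self) -> None:
        if self.hospital_beds <= 0:
            raise ValidationError("hospital_beds must be positive")
        if not 0 < self.occupancy <= 1:
            raise ValidationError("occupancy must lie in (0, 1]")
        if self.annual_litres_delivered <= 0:
            raise ValidationError("annual_litres_delivered must be positive")
        if self.recurrent_usd_per_year < 0 or self.annual_refill_usd < 0:
            raise ValidationError("recurrent and refill spend must be >= 0")


@dataclass(frozen=True)
class OxygenUseProfile:
    """A severity's oxygen demand: flow rate and hours on oxygen per day."""

    severity: Severity
    flow_l_per_min: float
    hours_per_day: float

    def __post_init__(self) -> None:
        if self.flow_l_per_min < 0:
            raise ValidationError("flow_l_per_min must be >= 0")
        if not 0 <= self.hours_per_day <= 24:
            raise ValidationError("hours_per_day must lie in [0, 24]")


def scenario_annual_cost(scenario: OxygenScenario, ctx: CostingContext) -> float:
    """Total annual cost of the supply scenario in USD."""
    capital = sum(
        annualize_capital(price, life, ctx.discount_rate)
        for price, life in scenario.capital_components
    )
    return capital + scenario.recurrent_usd_per_year + scenario.annual_refill_usd


def cost_per_litre(scenario: OxygenScenario, ctx: CostingContext) -> float:
    """USD per litre of delivered oxygen under the scenario."""
    return scenario_annual_cost(scenario, ctx) / scenario.annual_litres_delivered


def oxygen_cost_per_patient_day(
    profile: OxygenUseProfile, usd_per_litre: float
) -> float:
    """Price a flow-rate profile: flow x 60 min/h x hours/day x USD/L."""
    if usd_per_litre < 0:
        raise ValidationError("usd_per_litre must be >= 0")
    return profile.flow_l_per_min * 60.0 * profile.hours_per_day * usd_per_litre
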