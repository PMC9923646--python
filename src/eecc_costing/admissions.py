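"""Per-admission costs and the severity-mix weighted headline cost.

Per-admission cost is per-day cost x average length of stay (LOS).  LOS is
data, not a constant: the defaults shipped here are reverse-engineered from
the per-stay rows of the reference tables (dividing per-stay by per-day
cost) and are deliberately overridable — moderate 3 days, severe 8 days,
critical 8 (TZ) / 14 (KE) days at the essential level, and 8–14 days at the
advanced level.  The headline "cost of critical illness care" combines the
severe and critical per-day costs with population weights (74% severe, 26%
critical among the critically ill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ingredients import CareLevel, Country, Severity, ValidationError
from .valuation import round_half_up


@dataclass(frozen=True)
class LosTable:
    """Average length of stay in days per (country, care level, severity)."""

    days: dict[tuple[Country, CareLevel, Severity], float]

    def __post_init__(self) -> None:
        for key, d in self.days.items():
            if d <= 0:
                raise ValidationError(f"length of stay must be positive, got {d} for {key}")

    def get(self, country: Country, care_level: CareLevel, severity: Severity) -> float:
        return self.days[(country, care_level, severity)]


def default_los_table() -> LosTable:
    """LOS defaults back-divided from the reference per-stay rows."""
    E, A = CareLevel.EECC, CareLevel.ACC
    M, S, C = Severity.MODERATE, Severity.SEVERE, Severity.CRITICAL
    return LosTable(
        days={
            (Country.TZ, E, M): 3.0,
            (Country.TZ, E, S): 8.0,
            (Country.TZ, E, C): 8.0,
            (Country.KE, E, M): 3.0,
            (Country.KE, E, S): 8.0,
            (Country.KE, E, C): 14.0,
            (Country.TZ, A, S): 8.0,
            (Country.TZ, A, C): 14.0,
            (Country.KE, A, S): 14.0,
            (Country.KE, A, C): 14.0,
        }
    )


@dataclass(frozen=True)
class MixWeights:
    """Population weights of severe vs critical among the critically ill."""

    w_severe: float = 0.74
    w_critical: float = 0.26

    def __post_init__(self) -> None:
        if not 0 <= self.w_severe <= 1 or not 0 <= self.w_critical <= 1:
            raise ValidationError("mix weights must lie in [0, 1]")
        if abs(self.w_severe + self.w_critical - 1.0) > 1e-9:
            raise ValidationError("mix weights must sum to 1")


def cost_per_admission(per_day_usd: float, los_days: float) -> float:
    """Per-admission cost = per-day cost x LOS, reported at 2 dp."""
    if per_day_usd < 0 or los_days < 0:
        raise ValidationError("per-day cost and LOS must be >= 0")
    return round_half_up(per_day_usd * los_days, 2)


def weighted_daily_cost(
    severe_usd: float, critical_usd: float, w: MixWeights = MixWeights()
) -> float:
    """Severity-mix weighted per-day cost (unrounded).

    Round with :func:`headline` for whole-dollar reporting.
    """
    return w.w_severe * severe_usd + w.w_critical * critical_usd


def headline(usd: float) -> float:
    """Whole-dollar headline rounding (half-up)."""
    return round_half_up(usd, 0)
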