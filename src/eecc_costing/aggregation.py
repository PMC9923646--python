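"""Aggregation of valued lines into per-patient-day cost breakdowns.

A :class:`CostBreakdown` is the unit of reporting: for one country,
severity and care level it holds the USD per patient-day of each of the
eight cost categories, their total, and percentage shares.  Shares are
reported as integers at or above 1% and to one decimal below 1%, mirroring
the mixed precision of the published-style tables.

The hotel category is carried in breakdowns but is, strictly, not part of
the incremental critical-care cost (beds and overheads exist regardless);
``total_excluding_hotel`` exposes the stricter total while the default
total includes hotel to match the printed-table convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .ingredients import (
    CareLevel,
    CostCategory,
    Country,
    Severity,
    ValidationError,
)
from .valuation import LineDailyCost, round_half_up


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category USD/patient-day for one country x severity x care level."""

    country: Country
    severity: Severity
    care_level: CareLevel
    per_category_usd: dict[CostCategory, float]

    @property
    def total_usd_per_day(self) -> float:
        return sum(self.per_category_usd.values())

    @property
    def total_excluding_hotel(self) -> float:
        return self.total_usd_per_day - self.per_category_usd.get(
            CostCategory.HOTEL, 0.0
        )

    @property
    def shares_pct(self) -> dict[CostCategory, float]:
        """Unrounded percentage shares; empty when the total is zero."""
        total = self.total_usd_per_day
        if total == 0:
            return {}
        return {c: 100.0 * v / total for c, v in self.per_category_usd.items()}

    def shares_rounded(self) -> dict[CostCategory, float]:
        """Display shares: integer at >= 1%, one decimal below 1%.

        Integer shares are apportioned by largest remainder so the rounded
        shares sum to 100 within the sub-percent rounding slack (<= 0.5).
        """
        shares = self.shares_pct
        if not shares:
            return {}
        small = {c: round_half_up(s, 1) for c, s in shares.items() if s < 1.0}
        large = {c: s for c, s in shares.items() if s >= 1.0}
        out = dict(small)
        if large:
            target = int(round_half_up(100.0 - sum(small.values()), 0))
            floors = {c: math.floor(s) for c, s in large.items()}
            leftover = max(0, target - sum(floors.values()))
            by_remainder = sorted(
                large, key=lambda c: large[c] - floors[c], reverse=True
            )
            for i, c in enumerate(by_remainder):
                bump = leftover // len(large) + (1 if i < leftover % len(large) else 0)
                out[c] = float(floors[c] + bump)
        return out


def _round_share(share: float) -> float:
    if share >= 1.0:
        return round_half_up(share, 0)
    return round_half_up(share, 1)


def cost_per_patient_day(
    lines: list[LineDailyCost],
    country: Country,
    severity: Severity,
    care_level: CareLevel,
) -> CostBreakdown:
    """Sum valued lines into a breakdown.

    ``lines`` must already be filtered to the requested care level (the
    essential package excludes advanced-only lines).  Lines carrying a
    country tag must match ``country``.
    """
    per_category: dict[CostCategory, float] = {c: 0.0 for c in CostCategory}
    for line in lines:
        if line.country is not None and line.country != country:
            raise ValidationError(
                f"line {line.item_id!r} is for {line.country.value}, "
                f"not {country.value}"
            )
        per_category[line.category] += line.usd_per_patient_day
    return CostBreakdown(
        country=country,
        severity=severity,
        care_level=care_level,
        per_category_usd=per_category,
    )


def category_share(breakdown: CostBreakdown, category: CostCategory) -> float:
    """Rounded percentage share of one category (integer >= 1%, else 1 dp)."""
    total = breakdown.total_usd_per_day
    if total <= 0:
        raise ValidationError("category share undefined for a zero total")
    return _round_share(100.0 * breakdown.per_category_usd.get(category, 0.0) / total)


@dataclass(frozen=True)
class LevelComparison:
    """Ratio and per-category deltas between advanced and essential care."""

    country: Country
    severity: Severity
    ratio: float
    per_category_delta: dict[CostCategory, float]


def compare_levels(eecc: CostBreakdown, acc: CostBreakdown) -> LevelComparison:
    """ACC/EECC total ratio and per-category cost deltas.

    Requires matching country and severity; the advanced package, being a
    superset of the essential one, must not cost less.
    """
    if eecc.country != acc.country or eecc.severity != acc.severity:
        raise ValidationError("breakdowns must share country and severity")
    if eecc.total_usd_per_day <= 0:
        raise ValidationError("essential-care total must be positive")
    if acc.total_usd_per_day < eecc.total_usd_per_day:
        raise ValidationError(
            "advanced care cannot cost less than essential care "
            f"({acc.total_usd_per_day:.2f} < {eecc.total_usd_per_day:.2f})"
        )
    deltas = {
        c: acc.per_category_usd.get(c, 0.0) - eecc.per_category_usd.get(c, 0.0)
        for c in CostCategory
    }
    return LevelComparison(
        country=eecc.country,
        severity=eecc.severity,
        ratio=acc.total_usd_per_day / eecc.total_usd_per_day,
        per_category_delta=deltas,
    )
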