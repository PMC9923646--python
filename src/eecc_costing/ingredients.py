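"""Domain model for ingredients-based costing of critical-care services.

The costing is *normative* and *incremental*: it prices the resources a
hospital must have in place to deliver a defined standard of critical care
(essential, EECC; or advanced, ACC) over and above the definitive, hotel
and other care already provided.  Every costed item is a :class:`ResourceLine`
— an ingredient with a per-patient-day quantity for each illness severity —
joined to a :class:`UnitPrice` from a price book.

Severity follows the WHO COVID-19 grading used as the tracer condition:
*moderate* patients are not critically ill and consume resources only in the
identification stream (vital-signs monitoring to detect deterioration);
*severe* and *critical* patients consume identification plus treatment
resources.  Advanced critical care is defined as a superset of the essential
package: ACC line sets always contain the EECC lines plus ACC-only extras.

CSV schemas (RFC-4180, UTF-8, "." decimal separator) are fixed:

resource table
    ``item_id,name,category,stream,applicability,qty_moderate,qty_severe,qty_critical,unit``
price book
    ``item_id,price,currency,cost_type,useful_life_years,needs_uplift,source``
salary schedule
    ``cadre,grade,annual_salary,currency,country``

``applicability`` is ``EECC``, ``ACC`` or ``both``; a line needed at both
care levels is tagged ``both`` rather than duplicated, which prevents double
counting when ACC totals are built as EECC + extras.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class CostModelError(Exception):
    """Base class for model construction and I/O errors."""


class SchemaError(CostModelError):
    """A CSV file does not match the documented column schema."""


class ValidationError(CostModelError):
    """A parsed value violates a domain invariant."""


class Severity(enum.IntEnum):
    """Illness severity; ordering moderate < severe < critical is total."""

    MODERATE = 0
    SEVERE = 1
    CRITICAL = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown severity {label!r}; expected one of "
                f"{[s.label for s in cls]}"
            ) from None


class CareLevel(str, enum.Enum):
    """Care package: essential (EECC) or advanced (ACC, a superset of EECC)."""

    EECC = "EECC"
    ACC = "ACC"


class CareStream(str, enum.Enum):
    """Activity stream: identification of critical illness, or its treatment."""

    IDENTIFICATION = "identification"
    TREATMENT = "treatment"


class CostCategory(str, enum.Enum):
    """The eight reporting categories of the cost breakdown tables."""

    HOTEL = "hotel"
    STAFFING = "staffing"
    OXYGEN = "oxygen"
    PHARMACEUTICALS = "pharmaceuticals"
    NONPHARMA_CAPITAL = "nonpharma_capital"
    NONPHARMA_RECURRENT = "nonpharma_recurrent"
    PPE = "ppe"
    DIAGNOSTICS = "diagnostics"


#: Human-readable row labels used in rendered tables.
CATEGORY_LABELS: dict[CostCategory, str] = {
    CostCategory.HOTEL: "Hotel costs (accommodation + overheads)",
    CostCategory.STAFFING: "Staffing costs",
    CostCategory.OXYGEN: "Oxygen provision",
    CostCategory.PHARMACEUTICALS: "Pharmaceuticals (Medicines etc.)",
    CostCategory.NONPHARMA_CAPITAL: "Non-pharmaceutical costs (capital)",
    CostCategory.NONPHARMA_RECURRENT: "Non-pharmaceutical costs (fluids, devices etc. costs)",
    CostCategory.PPE: "Personal protective equipment (PPE)",
    CostCategory.DIAGNOSTICS: "Support services (diagnostics)",
}


class Currency(str, enum.Enum):
    TZS = "TZS"
    KES = "KES"
    USD = "USD"


class Country(str, enum.Enum):
    TZ = "TZ"
    KE = "KE"


class CostType(str, enum.Enum):
    CAPITAL = "capital"
    RECURRENT = "recurrent"
    STAFF_TIME = "staff_time"


@dataclass(frozen=True)
class Money:
    """A non-negative amount in TZS, KES or USD."""

    amount: float
    currency: Currency

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValidationError(f"money amount must be >= 0, got {self.amount}")
        if not isinstance(self.currency, Currency):
            object.__setattr__(self, "currency", Currency(self.currency))


@dataclass(frozen=True)
class UnitPrice:
    """Price-book entry for one item.

    ``useful_life_years`` must be present iff ``cost_type`` is capital;
    ``needs_uplift`` marks goods whose quoted price excludes shipping and
    therefore receives the transport/insurance percentage uplift.
    For ``staff_time`` entries ``price`` is an annual salary.
    """

    item_id: str
    price: Money
    cost_type: CostType
    useful_life_years: float | None = None
    needs_uplift: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.cost_type == CostType.CAPITAL:
            if self.useful_life_years is None or self.useful_life_years <= 0:
                raise ValidationError(
                    f"capital item {self.item_id!r} needs a positive "
                    f"useful_life_years, got {self.useful_life_years}"
                )
        elif self.useful_life_years is not None:
            raise ValidationError(
                f"non-capital item {self.item_id!r} must not carry a useful life"
            )


@dataclass(frozen=True)
class ResourceLine:
    """One costed ingredient.

    ``quantity_per_day`` holds the average per-patient-day quantity for each
    of the three severities, in the item's natural unit: minutes for staff
    time, litres for oxygen, counts for consumables, device-fractions (share
    of a device's day attributable to one patient) for equipment.
    """

    item_id: str
    name: str
    category: CostCategory
    stream: CareStream
    applicability: frozenset[CareLevel]
    quantity_per_day: Mapping[Severity, float]
    unit: str = ""

    def __post_init__(self) -> None:
        missing = [s.label for s in Severity if s not in self.quantity_per_day]
        if missing:
            raise ValidationError(
                f"line {self.item_id!r} lacks quantities for severities {missing}"
            )
        for sev, qty in self.quantity_per_day.items():
            if qty < 0:
                raise ValidationError(
                    f"line {self.item_id!r} has negative quantity {qty} "
                    f"for severity {Severity(sev).label}"
                )
        if not self.applicability:
            raise ValidationError(f"line {self.item_id!r} has empty applicability")

    def applies_to(self, level: CareLevel) -> bool:
        return level in self.applicability


@dataclass(frozen=True)
class StaffCadre:
    """A staff cadre with its public-sector salary grade."""

    cadre: str
    grade: str
    annual_salary: Money
    country: Country

    def __post_init__(self) -> None:
        if self.annual_salary.amount <= 0:
            raise ValidationError(
                f"cadre {self.cadre!r} must have a positive annual salary"
            )


RESOURCE_COLUMNS = [
    "item_id",
    "name",
    "category",
    "stream",
    "applicability",
    "qty_moderate",
    "qty_severe",
    "qty_critical",
    "unit",
]
PRICE_COLUMNS = [
    "item_id",
    "price",
    "currency",
    "cost_type",
    "useful_life_years",
    "needs_uplift",
    "source",
]
SALARY_COLUMNS = ["cadre", "grade", "annual_salary", "currency", "country"]


def _check_header(header: list[str] | None, expected: list[str], path: object) -> None:
    if header is None:
        raise SchemaError(f"{path}: empty file, expected header {expected}")
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _applicability_from_tag(tag: str, row_no: int) -> frozenset[CareLevel]:
    tag = tag.strip()
    if tag.lower() == "both":
        return frozenset({CareLevel.EECC, CareLevel.ACC})
    try:
        return frozenset({CareLevel(tag.upper())})
    except ValueError:
        raise ValidationError(
            f"row {row_no}: applicability must be EECC, ACC or both, got {tag!r}"
        ) from None


def _applicability_tag(levels: frozenset[CareLevel]) -> str:
    if levels == frozenset({CareLevel.EECC, CareLevel.ACC}):
        return "both"
    return next(iter(levels)).value


def _num(text: str) -> str:
    """Canonical decimal rendering used by all writers (lossless round-trip)."""
    return text


def _fmt(x: float) -> str:
    return str(float(x))


def read_resource_table(path: str | Path) -> list[ResourceLine]:
    """Read a resource table CSV into validated :class:`ResourceLine` objects."""
    path = Path(path)
    lines: list[ResourceLine] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, RESOURCE_COLUMNS, path)
        for row_no, row in enumerate(reader, start=2):
            cat_raw = row["category"].strip()
            try:
                category = CostCategory(cat_raw)
            except ValueError:
                raise ValidationError(
                    f"{path}:{row_no}: unknown category {cat_raw!r}; allowed: "
                    f"{[c.value for c in CostCategory]}"
                ) from None
            try:
                stream = CareStream(row["stream"].strip())
            except ValueError:
                raise ValidationError(
                    f"{path}:{row_no}: unknown stream {row['stream']!r}; allowed: "
                    f"{[s.value for s in CareStream]}"
                ) from None
            try:
                quantities = {
                    Severity.MODERATE: float(row["qty_moderate"]),
                    Severity.SEVERE: float(row["qty_severe"]),
                    Severity.CRITICAL: float(row["qty_critical"]),
                }
            except ValueError as exc:
                raise ValidationError(f"{path}:{row_no}: bad quantity ({exc})") from None
            try:
                line = ResourceLine(
                    item_id=row["item_id"].strip(),
                    name=row["name"],
                    category=category,
                    stream=stream,
                    applicability=_applicability_from_tag(row["applicability"], row_no),
                    quantity_per_day=quantities,
                    unit=row["unit"],
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{row_no}: {exc}") from None
            lines.append(line)
    return lines


def write_resource_table(lines: Iterable[ResourceLine], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESOURCE_COLUMNS)
        for ln in lines:
            writer.writerow(
                [
                    ln.item_id,
                    ln.name,
                    ln.category.value,
                    ln.stream.value,
                    _applicability_tag(ln.applicability),
                    _fmt(ln.quantity_per_day[Severity.MODERATE]),
                    _fmt(ln.quantity_per_day[Severity.SEVERE]),
                    _fmt(ln.quantity_per_day[Severity.CRITICAL]),
                    ln.unit,
                ]
            )


def read_pricebook(path: str | Path) -> dict[str, UnitPrice]:
    """Read a price book CSV into an ``item_id -> UnitPrice`` map."""
    path = Path(path)
    prices: dict[str, UnitPrice] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, PRICE_COLUMNS, path)
        for row_no, row in enumerate(reader, start=2):
            item_id = row["item_id"].strip()
            if item_id in prices:
                raise ValidationError(f"{path}:{row_no}: duplicate item_id {item_id!r}")
            life_raw = row["useful_life_years"].strip()
            life = float(life_raw) if life_raw else None
            try:
                price = UnitPrice(
                    item_id=item_id,
                    price=Money(float(row["price"]), Currency(row["currency"].strip())),
                    cost_type=CostType(row["cost_type"].strip()),
                    useful_life_years=life,
                    needs_uplift=row["needs_uplift"].strip().lower()
                    in {"1", "true", "yes"},
                    source=row["source"],
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{row_no}: {exc}") from None
            prices[item_id] = price
    return prices


def write_pricebook(prices: Mapping[str, UnitPrice], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PRICE_COLUMNS)
        for item_id in prices:
            p = prices[item_id]
            writer.writerow(
                [
                    p.item_id,
                    _fmt(p.price.amount),
                    p.price.currency.value,
                    p.cost_type.value,
                    "" if p.useful_life_years is None else _fmt(p.useful_life_years),
                    "true" if p.needs_uplift else "false",
                    p.source,
                ]
            )


def read_salary_schedule(path: str | Path) -> list[StaffCadre]:
    path = Path(path)
    cadres: list[StaffCadre] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SALARY_COLUMNS, path)
        for row_no, row in enumerate(reader, start=2):
            try:
                cadres.append(
                    StaffCadre(
                        cadre=row["cadre"].strip(),
                        grade=row["grade"].strip(),
                        annual_salary=Money(
                            float(row["annual_salary"]),
                            Currency(row["currency"].strip()),
                        ),
                        country=Country(row["country"].strip()),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{row_no}: {exc}") from None
    return cadres


def write_salary_schedule(cadres: Iterable[StaffCadre], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SALARY_COLUMNS)
        for c in cadres:
            writer.writerow(
                [
                    c.cadre,
                    c.grade,
                    _fmt(c.annual_salary.amount),
                    c.annual_salary.currency.value,
                    c.country.value,
                ]
            )


@dataclass
class ValidationReport:
    """Report-only consistency check between a line set and a price book."""

    unpriced_lines: list[str] = field(default_factory=list)
    unused_prices: list[str] = field(default_factory=list)
    moderate_treatment_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.unpriced_lines
            or self.unused_prices
            or self.moderate_treatment_violations
        )


def validate_model(
    lines: Iterable[ResourceLine], prices: Mapping[str, UnitPrice]
) -> ValidationReport:
    """Cross-check lines against prices and the moderate-severity rule.

    Moderate patients are not critically ill: at the essential care level they
    consume identification-stream resources only, so a treatment-stream line
    applicable to EECC with a nonzero moderate quantity is flagged.
    """
    report = ValidationReport()
    seen_ids = set()
    for line in lines:
        seen_ids.add(line.item_id)
        if line.item_id not in prices:
            report.unpriced_lines.append(line.item_id)
        if (
            line.stream == CareStream.TREATMENT
            and line.applies_to(CareLevel.EECC)
            and line.quantity_per_day[Severity.MODERATE] > 0
        ):
            report.moderate_treatment_violations.append(line.item_id)
    report.unused_prices.extend(pid for pid in prices if pid not in seen_ids)
    return report


def canonical_csv(text: str) -> str:
    """Normalise a CSV string: CRLF -> LF, strip trailing blank line."""
    return io.StringIO(text.replace("\r\n", "\n")).getvalue().rstrip("\n") + "\n"
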