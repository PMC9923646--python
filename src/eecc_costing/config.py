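"""Run configuration: one YAML file describing a complete costing run.

A :class:`RunConfig` bundles the input paths (resource table, price book,
salary schedule — all optional; when absent the packaged category-level
reference model is used), the valuation constants, the scenario
specification, length-of-stay and severity-mix assumptions, and the output
directory.  Configs round-trip through :func:`save_config` /
:func:`load_config`, and :func:`config_hash` gives the digest recorded in
the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .admissions import LosTable, MixWeights, default_los_table
from .ingredients import CareLevel, CostCategory, Country, Severity, ValidationError
from .scenarios import ScenarioSpec
from .valuation import CostingContext


@dataclass
class RunConfig:
    """Everything needed to reproduce a costing run."""

    resource_table: Path | None = None
    pricebook: Path | None = None
    salary_schedule: Path | None = None
    context: CostingContext = field(default_factory=CostingContext)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    los_table: LosTable = field(default_factory=default_los_table)
    mix_weights: MixWeights = field(default_factory=MixWeights)
    output_dir: Path = Path("costing_output")

    def validate_paths(self) -> None:
        for name in ("resource_table", "pricebook", "salary_schedule"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config key {name!r}: path {p} does not exist")


def _context_to_dict(ctx: CostingContext) -> dict:
    d = dataclasses.asdict(ctx)
    d["ci_quantiles"] = list(ctx.ci_quantiles)
    return d


def _scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "oxygen_multipliers": list(spec.oxygen_multipliers),
        "pharma_multipliers": list(spec.pharma_multipliers),
        "staffing_mode": spec.staffing_mode,
        "per_category_overrides": {
            cat.value: list(bounds)
            for cat, bounds in spec.per_category_overrides.items()
        },
    }


def to_dict(cfg: RunConfig) -> dict:
    return {
        "inputs": {
            "resource_table": None if cfg.resource_table is None else str(cfg.resource_table),
            "pricebook": None if cfg.pricebook is None else str(cfg.pricebook),
            "salary_schedule": None
            if cfg.salary_schedule is None
            else str(cfg.salary_schedule),
        },
        "context": _context_to_dict(cfg.context),
        "scenario": _scenario_to_dict(cfg.scenario),
        "los_days": {
            f"{c.value}/{lvl.value}/{sev.label}": d
            for (c, lvl, sev), d in sorted(
                cfg.los_table.days.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2]),
            )
        },
        "mix_weights": {
            "w_severe": cfg.mix_weights.w_severe,
            "w_critical": cfg.mix_weights.w_critical,
        },
        "output_dir": str(cfg.output_dir),
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(to_dict(cfg), sort_keys=True), encoding="utf-8"
    )


def _parse_los(raw: dict) -> LosTable:
    days: dict = {}
    for key, d in raw.items():
        try:
            country, level, sev = key.split("/")
            days[
                (Country(country), CareLevel(level), Severity.from_label(sev))
            ] = float(d)
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"config key 'los_days': bad entry {key!r} ({exc})")
    return LosTable(days=days)


def from_dict(raw: dict) -> RunConfig:
    def section(name: str, default: dict | None = None) -> dict:
        val = raw.get(name, default if default is not None else {})
        if not isinstance(val, dict):
            raise ValidationError(f"config key {name!r} must be a mapping")
        return val

    inputs = section("inputs")

    def path_or_none(key: str) -> Path | None:
        val = inputs.get(key)
        return None if val in (None, "") else Path(val)

    try:
        ctx_raw = section("context")
        ctx_raw = {**ctx_raw}
        if "ci_quantiles" in ctx_raw:
            ctx_raw["ci_quantiles"] = tuple(ctx_raw["ci_quantiles"])
        context = CostingContext(**ctx_raw)
    except TypeError as exc:
        raise ValidationError(f"config key 'context': {exc}")

    try:
        sc_raw = {**section("scenario")}
        overrides = {
            CostCategory(cat): tuple(bounds)
            for cat, bounds in sc_raw.pop("per_category_overrides", {}).items()
        }
        for key in ("oxygen_multipliers", "pharma_multipliers"):
            if key in sc_raw:
                sc_raw[key] = tuple(sc_raw[key])
        scenario = ScenarioSpec(per_category_overrides=overrides, **sc_raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"config key 'scenario': {exc}")

    los = _parse_los(section("los_days")) if raw.get("los_days") else default_los_table()

    try:
        mw_raw = section("mix_weights")
        mix = MixWeights(**mw_raw) if mw_raw else MixWeights()
    except TypeError as exc:
        raise ValidationError(f"config key 'mix_weights': {exc}")

    return RunConfig(
        resource_table=path_or_none("resource_table"),
        pricebook=path_or_none("pricebook"),
        salary_schedule=path_or_none("salary_schedule"),
        context=context,
        scenario=scenario,
        los_table=los,
        mix_weights=mix,
        output_dir=Path(raw.get("output_dir", "costing_output")),
    )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return from_dict(raw)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical YAML serialization."""
    canonical = yaml.safe_dump(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
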