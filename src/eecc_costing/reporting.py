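"""Table writers: breakdown, PSA and scenario-range tables, plus run manifests.

Tables are emitted twice from the same frame: RFC-4180 CSV for downstream
use, and an aligned text rendering whose row labels match the reference
breakdown tables.  Every run also writes ``run_manifest.json`` — config
hash, seed, draw count and package version — sufficient to reproduce the
outputs bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .admissions import LosTable, cost_per_admission
from .aggregation import CostBreakdown
from .ingredients import CATEGORY_LABELS, CareLevel, CostCategory
from .scenarios import PSAResult, ScenarioBounds
from .valuation import round_half_up

TOTAL_ROW = "Patient cost/day USD"
STAY_ROW = "Cost per patient per stay in hospital"


def _cell_label(b: CostBreakdown) -> str:
    return f"{b.country.value} {b.severity.label}"


def breakdown_table(
    breakdowns: list[CostBreakdown], los_table: LosTable | None = None
) -> pd.DataFrame:
    """One care level's table: category rows x (country, severity) columns.

    Each cell column carries USD/day (2 dp) and the rounded percentage
    share; total and per-stay rows close the table.
    """
    columns: dict[str, list] = {}
    for b in breakdowns:
        shares = b.shares_rounded()
        usd_col = [
            round_half_up(b.per_category_usd.get(cat, 0.0), 2) for cat in CostCategory
        ]
        pct_col = [shares.get(cat, 0.0) for cat in CostCategory]
        usd_col.append(round_half_up(b.total_usd_per_day, 2))
        pct_col.append(100.0 if b.total_usd_per_day > 0 else 0.0)
        if los_table is not None:
            los = los_table.get(b.country, b.care_level, b.severity)
            usd_col.append(cost_per_admission(b.total_usd_per_day, los))
            pct_col.append(float("nan"))
        columns[f"{_cell_label(b)} USD"] = usd_col
        columns[f"{_cell_label(b)} %"] = pct_col
    index = [CATEGORY_LABELS[cat] for cat in CostCategory] + [TOTAL_ROW]
    if los_table is not None:
        index.append(STAY_ROW)
    return pd.DataFrame(columns, index=index)


def psa_table(results: dict[str, PSAResult]) -> pd.DataFrame:
    """PSA summary in 'mean (low-high)' style, one row per cell."""
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "cell": label,
                "mean (95% CI) USD/day": (
                    f"{round_half_up(r.mean_usd, 2):.2f} "
                    f"({round_half_up(r.ci_low_usd, 2):.2f}-"
                    f"{round_half_up(r.ci_high_usd, 2):.2f})"
                ),
                "draws": r.draws,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def scenario_table(bounds: dict[str, ScenarioBounds]) -> pd.DataFrame:
    """Low/reference/high total USD per day, one row per cell."""
    rows = []
    for label, b in bounds.items():
        rows.append(
            {
                "cell": label,
                "low": round_half_up(b.total_low, 2),
                "reference": round_half_up(b.total_reference, 2),
                "high": round_half_up(b.total_high, 2),
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def write_table(df: pd.DataFrame, outdir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write a frame as ``<stem>.csv`` and aligned ``<stem>.txt``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    txt_path = outdir / f"{stem}.txt"
    df.to_csv(csv_path, lineterminator="\n")
    txt_path.write_text(df.to_string() + "\n", encoding="utf-8")
    return csv_path, txt_path


def write_manifest(
    outdir: str | Path, *, config_digest: str, seed: int, draws: int | None = None
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "eecc-costing",
        "version": __version__,
        "config_sha256": config_digest,
        "seed": seed,
    }
    if draws is not None:
        manifest["draws"] = draws
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
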