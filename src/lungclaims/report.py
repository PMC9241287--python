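"""Pipeline orchestration and descriptive output tables.

Runs the full phenotyping chain (selection -> lines/types -> care ->
burden) over a claims extract and writes the descriptive tables the
analysis is built around: the attrition flow with one disjoint reason
per excluded patient, crosstabs of stage / demographics / treatment
group / therapist against the cancer-type call (counts with
within-column percentages), and the aggregated burden series.

The run is deterministic: identical inputs and configuration produce a
byte-identical output bundle.  The manifest records the configuration
hash and code-table version so a bundle can be traced to its inputs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .burden import build_burden
from .care import CareConfig, build_care
from .codes import CodeTable, load_default_table
from .cohort import EXCLUSION_ORDER, CohortConfig, select_cohort
from .io import read_claims
from .model import PatientRecord
from .therapy import TherapyConfig, build_lines, categorize_untreated
from .model import Quarter

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "attrition_table",
    "crosstab",
    "pct",
]

log = logging.getLogger("lungclaims")


def pct(numerator: float, denominator: float) -> str:
    """Percentage with one decimal, half-up rounding ("26.0")."""
    if denominator == 0:
        return ""
    v = Decimal(numerator) / Decimal(denominator) * 100
    return str(v.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class PipelineConfig(BaseModel):
    """End-to-end run configuration (YAML-loadable)."""

    input_dir: str
    output_dir: str
    period_start: dt.date = dt.date(2015, 1, 1)
    period_end: dt.date = dt.date(2016, 12, 31)
    observation_end: dt.date = dt.date(2018, 12, 31)
    window_days: int = Field(default=30, ge=1)
    inpatient_lookback_days: int = Field(default=14, ge=0)
    code_table: str | None = None
    surgery_codes: str | None = None
    burden_by_region: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def cohort(self) -> CohortConfig:
        return CohortConfig(
            period_start=self.period_start,
            period_end=self.period_end,
            observation_end=self.observation_end,
        )

    def therapy(self) -> TherapyConfig:
        return TherapyConfig(window_days=self.window_days)

    def care(self) -> CareConfig:
        return CareConfig(
            inpatient_lookback_days=self.inpatient_lookback_days,
            window_days=self.window_days,
        )

    def load_table(self) -> CodeTable:
        if self.code_table:
            table = CodeTable.from_csv(self.code_table)
        else:
            table = load_default_table(include_surgery=False)
        if self.surgery_codes:
            table = table.merge(CodeTable.from_csv(self.surgery_codes))
        else:
            from .codes import load_surgery_table

            table = table.merge(load_surgery_table())
        return table


@dataclass
class RunReport:
    attrition: pd.DataFrame
    selection: pd.DataFrame
    lines: pd.DataFrame
    types: pd.DataFrame
    first_line_labels: pd.DataFrame
    care: pd.DataFrame
    burden: pd.DataFrame
    crosstabs: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def attrition_table(selection: pd.DataFrame) -> pd.DataFrame:
    """Attrition flow: candidates, per-reason exclusions, included."""
    total = len(selection)
    rows = [{"step": "candidates", "n": total, "pct": pct(total, total) if total else ""}]
    for reason in EXCLUSION_ORDER:
        n = int((selection["exclusion_reason"] == reason.value).sum()) if total else 0
        rows.append({"step": f"excluded_{reason.value}", "n": n, "pct": pct(n, total)})
    inc = int((selection["status"] == "included").sum()) if total else 0
    rows.append({"step": "included", "n": inc, "pct": pct(inc, total)})
    return pd.DataFrame(rows, columns=["step", "n", "pct"])


def crosstab(df: pd.DataFrame, row_dim: str, col_dim: str) -> pd.DataFrame:
    """Counts with within-column percentages over non-missing entries.

    Missing entries (empty strings) are reported in a separate
    ``missing`` row, excluded from the percentage denominator.
    """
    for dim in (row_dim, col_dim):
        if dim not in df.columns:
            raise ValueError(f"unknown dimension {dim!r}")
    data = df[[row_dim, col_dim]].fillna("")
    cols = sorted(x for x in data[col_dim].unique() if x != "")
    known = data[(data[row_dim] != "") & (data[row_dim] != "unknown")]
    rows = sorted(known[row_dim].unique())
    out_rows = []
    for r in rows:
        row: dict[str, object] = {row_dim: r}
        for c in cols:
            n = int(((known[row_dim] == r) & (known[col_dim] == c)).sum())
            denom = int((known[col_dim] == c).sum())
            row[f"{c}_n"] = n
            row[f"{c}_pct"] = pct(n, denom)
        out_rows.append(row)
    n_missing = data[(data[row_dim] == "") | (data[row_dim] == "unknown")]
    if len(n_missing):
        row = {row_dim: "missing"}
        for c in cols:
            row[f"{c}_n"] = int((n_missing[col_dim] == c).sum())
            row[f"{c}_pct"] = ""
        out_rows.append(row)
    columns = [row_dim] + [f"{c}_{s}" for c in cols for s in ("n", "pct")]
    return pd.DataFrame(out_rows, columns=columns)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig, records: list[PatientRecord] | None = None
) -> RunReport:
    """Execute select -> lines/types -> care -> burden and write tables."""
    logging.basicConfig(level=cfg.log_level)
    table = cfg.load_table()
    cohort_cfg, therapy_cfg, care_cfg = cfg.cohort(), cfg.therapy(), cfg.care()
    if records is None:
        records = read_claims(cfg.input_dir)
    by_id = {p.patient_id: p for p in records}
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    selection = select_cohort(records, cohort_cfg, table)
    log.info("select: %d candidates, %d included", len(selection),
             int((selection["status"] == "included").sum()))
    lines, types, episodes = build_lines(by_id, selection, table, therapy_cfg)
    log.info("lines: %d episodes, %d type calls", len(lines), len(types))
    care = build_care(by_id, selection, episodes, table, care_cfg)
    log.info("care: %d rows", len(care))
    burden = build_burden(
        by_id, selection, types, episodes, cohort_cfg, table, by_region=cfg.burden_by_region
    )
    log.info("burden: %d aggregated rows", len(burden))

    # first-line label: treatment group or other-treatment category
    label_rows = []
    included = selection[selection["status"] == "included"]
    care_first = care[care["context"] == "first"].set_index("patient_id")
    for _, row in included.iterrows():
        pid = row["patient_id"]
        first, _second = episodes.get(pid, (None, None))
        if first is not None:
            label = first.group.value
        else:
            flags = care_first.loc[pid] if pid in care_first.index else None
            label = categorize_untreated(
                by_id[pid],
                Quarter.parse(row["index_quarter"]),
                table,
                surgery_flag=bool(flags is not None and flags["surgery_flag"]),
                bronchoscopy_flag=bool(
                    flags is not None and flags["bronchoscopy_setting"] != "none"
                ),
                cfg=therapy_cfg,
            ).value
        label_rows.append({"patient_id": pid, "first_line_label": label})
    first_line_labels = pd.DataFrame(
        label_rows, columns=["patient_id", "first_line_label"]
    )

    attrition = attrition_table(selection)

    # crosstabs against the cancer-type call
    merged = included.merge(types, on="patient_id", how="left").merge(
        first_line_labels, on="patient_id", how="left"
    )
    merged = merged.merge(
        care_first.reset_index()[["patient_id", "therapist"]], on="patient_id", how="left"
    )
    crosstabs = {
        "stage_by_type": crosstab(merged, "stage", "call"),
        "age_by_type": crosstab(merged, "age_group", "call"),
        "gender_by_type": crosstab(merged, "gender", "call"),
        "region_by_type": crosstab(merged, "region", "call"),
        "group_by_type": crosstab(merged, "first_line_label", "call"),
        "therapist_by_type": crosstab(merged, "therapist", "call"),
    }

    manifest = {
        "package_version": __version__,
        "config": cfg.model_dump(mode="json"),
        "config_hash": _config_hash(cfg),
        "code_table_version": table.version,
        "n_records": len(records),
        "n_candidates": int(len(selection)),
        "n_included": int((selection["status"] == "included").sum()),
    }

    _write_csv(selection, out / "selection.csv")
    _write_csv(lines, out / "lines.csv")
    _write_csv(types, out / "types.csv")
    _write_csv(first_line_labels, out / "first_line_labels.csv")
    _write_csv(care, out / "care.csv")
    _write_csv(burden, out / "burden_long.csv")
    _write_csv(attrition, out / "attrition.csv")
    for name, df in crosstabs.items():
        _write_csv(df, out / f"crosstab_{name}.csv")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunReport(
        attrition=attrition,
        selection=selection,
        lines=lines,
        types=types,
        first_line_labels=first_line_labels,
        care=care,
        burden=burden,
        crosstabs=crosstabs,
        manifest=manifest,
    )
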