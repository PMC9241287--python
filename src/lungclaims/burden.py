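"""Disease- and treatment-related time expenditure per patient.

The burden of diagnosis and treatment is modeled as countable time
expenditure over relative quarters -4 ... +8 around the index quarter:
pharmacy visits (distinct dispensing dates), visits to a primary-care
physician and to specialists (distinct date x provider contacts), days
spent in inpatient hospital stays (closed intervals, split across
quarter boundaries by calendar membership), and outpatient hospital
treatments.

Eligible for this analysis are included patients with exactly one
treatment line (no second-line therapy, not untreated) whose diagnosis
satisfied the *outpatient* M2Q criterion.  Quarters outside a patient's
enrollment are recorded as missing, not zero, and drop out of the
denominator when series are averaged within strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import CohortConfig, outpatient_m2q
from .codes import CodeTable
from .model import (
    SPECIALIST_PROVIDERS,
    EventKind,
    PatientRecord,
    Provider,
    Quarter,
    Setting,
    StayMode,
)
from .therapy import LineEpisode

__all__ = [
    "RELATIVE_QUARTERS",
    "BURDEN_METRICS",
    "burden_eligible",
    "compute_burden",
    "aggregate_burden",
    "build_burden",
]

RELATIVE_QUARTERS = tuple(range(-4, 9))
BURDEN_METRICS = (
    "pharmacy_visits",
    "gp_visits",
    "specialist_visits",
    "inpatient_days",
    "outpatient_hospital_treatments",
)


def burden_eligible(
    p: PatientRecord,
    first: LineEpisode | None,
    second: LineEpisode | None,
    cfg: CohortConfig,
    table: CodeTable,
) -> bool:
    """Included, exactly one treatment line, outpatient-M2Q-confirmed."""
    if first is None or second is not None:
        return False
    return outpatient_m2q(p, cfg, table)


def _observed(p: PatientRecord, q: Quarter) -> bool:
    # a quarter counts as observed if any enrollment overlaps it
    return any(s <= q.end and e >= q.start for s, e in p.enrollment)


def compute_burden(p: PatientRecord, index_q: Quarter) -> pd.DataFrame:
    """Per-relative-quarter counts for one patient (NaN = unobserved)."""
    rows = []
    for r in RELATIVE_QUARTERS:
        q = index_q.shift(r)
        if not _observed(p, q):
            rows.append(
                {"patient_id": p.patient_id, "relative_quarter": r}
                | {m: math.nan for m in BURDEN_METRICS}
            )
            continue
        events = p.events_in_quarter(q)
        pharmacy = len({ev.date for ev in events if ev.kind is EventKind.DISPENSING})
        gp = len(
            {
                (ev.date, ev.provider)
                for ev in events
                if ev.kind is EventKind.CONTACT and ev.provider is Provider.PRIMARY_CARE
            }
        )
        spec = len(
            {
                (ev.date, ev.provider)
                for ev in events
                if ev.kind is EventKind.CONTACT and ev.provider in SPECIALIST_PROVIDERS
            }
        )
        inpatient_days = sum(
            s.days_in_quarter(q) for s in p.stays if s.mode is StayMode.INPATIENT
        )
        hosp_out = len(
            {
                ev.date
                for ev in events
                if ev.kind is EventKind.CONTACT
                and ev.provider is Provider.HOSPITAL
                and ev.setting is Setting.OUTPATIENT
            }
        )
        rows.append(
            {
                "patient_id": p.patient_id,
                "relative_quarter": r,
                "pharmacy_visits": pharmacy,
                "gp_visits": gp,
                "specialist_visits": spec,
                "inpatient_days": inpatient_days,
                "outpatient_hospital_treatments": hosp_out,
            }
        )
    return pd.DataFrame(rows)


def aggregate_burden(series: pd.DataFrame, strata: pd.DataFrame) -> pd.DataFrame:
    """Mean series per stratum, long format.

    *series* is the concatenation of per-patient :func:`compute_burden`
    frames; *strata* maps patient_id to a ``stratum`` label.  Missing
    (unobserved) quarters are excluded from the denominator; empty
    strata are omitted.
    """
    merged = series.merge(strata[["patient_id", "stratum"]], on="patient_id", how="inner")
    long = merged.melt(
        id_vars=["patient_id", "stratum", "relative_quarter"],
        value_vars=list(BURDEN_METRICS),
        var_name="metric",
        value_name="value",
    )
    grouped = (
        long.groupby(["stratum", "metric", "relative_quarter"])["value"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    grouped["mean"] = grouped["mean"].round(6)
    grouped["n"] = grouped["n"].astype(int)
    return grouped.sort_values(
        ["stratum", "metric", "relative_quarter"], kind="stable"
    ).reset_index(drop=True)


def build_burden(
    records: dict[str, PatientRecord],
    selection: pd.DataFrame,
    types: pd.DataFrame,
    episodes: dict[str, tuple[LineEpisode | None, LineEpisode | None]],
    cohort_cfg: CohortConfig,
    table: CodeTable,
    by_region: bool = True,
) -> pd.DataFrame:
    """Aggregated burden, stratified by cancer-type call (and region)."""
    included = selection[selection["status"] == "included"].set_index("patient_id")
    calls = types.set_index("patient_id")["call"]
    frames, strata_rows = [], []
    for pid, row in included.iterrows():
        p = records[pid]
        first, second = episodes.get(pid, (None, None))
        if not burden_eligible(p, first, second, cohort_cfg, table):
            continue
        index_q = Quarter.parse(row["index_quarter"])
        frames.append(compute_burden(p, index_q))
        stratum = calls.get(pid, "unclassifiable")
        if by_region:
            stratum = f"{stratum}/{row['region']}"
        strata_rows.append({"patient_id": pid, "stratum": stratum})
    if not frames:
        return pd.DataFrame(
            columns=["stratum", "metric", "relative_quarter", "mean", "n"]
        )
    series = pd.concat(frames, ignore_index=True)
    return aggregate_burden(series, pd.DataFrame(strata_rows))
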