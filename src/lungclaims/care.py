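"""Therapist attribution and detection of surgery, biomarker, bronchoscopy.

The "therapist" is the institution that coded the lung cancer diagnosis
in a given quarter (index quarter, first-line start quarter, second-line
start quarter).  When several coders appear, a fixed hierarchy decides:
inpatient hospital > outpatient hospital > oncologist > pulmonologist >
radiologist > internist > primary-care physician > other office-based
physician.

Diagnostic tests (biomarker EBM 19320-19322 / OPS 1-991x, 1-992x;
bronchoscopy OPS 1-690.0/1-690.1/1-620, EBM 09315/13662) are searched in
the index quarter plus the first month of first-line therapy (first-line
context) and from one month after the first-line start to one month
after the second-line start (second-line context).  A detected test
counts as inpatient if a hospital stay is documented in the 14 days
before the test date, otherwise as outpatient.

Surgery detection scans the index quarter and the quarter in which each
line starts, against a configurable OPS code set (the bundled default is
a synthetic placeholder family).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .codes import CodeSystem, CodeTable, Role
from .model import EventKind, PatientRecord, Provider, Quarter, Setting
from .therapy import LineEpisode, TherapyConfig

__all__ = [
    "CareConfig",
    "TherapistCall",
    "DiagnosticFlag",
    "attribute_therapist",
    "detect_biomarker",
    "detect_bronchoscopy",
    "detect_surgery",
    "build_care",
]


@dataclass(frozen=True)
class CareConfig:
    #: "two weeks": a test is inpatient if a hospital stay is documented
    #: within this many days before the test date
    inpatient_lookback_days: int = 14
    window_days: int = 30


#: Office-based specialty hierarchy (after the two hospital categories).
_SPECIALTY_ORDER = (
    Provider.ONCOLOGIST,
    Provider.PULMONOLOGIST,
    Provider.RADIOLOGIST,
    Provider.INTERNIST,
    Provider.PRIMARY_CARE,
    Provider.OTHER_OFFICE_BASED,
)


@dataclass(frozen=True)
class TherapistCall:
    patient_id: str
    context: str  # "index" | "first_line" | "second_line"
    category: str  # "hospital_inpatient" | "hospital_outpatient" | "other_physician" | "unknown"
    specialty: Provider | None = None


@dataclass(frozen=True)
class DiagnosticFlag:
    patient_id: str
    kind: str  # "biomarker" | "bronchoscopy" | "surgery"
    line_context: str  # "first" | "second"
    setting: Setting = Setting.NONE
    date: dt.date | None = None

    @property
    def detected(self) -> bool:
        return self.setting is not Setting.NONE or self.date is not None


def attribute_therapist(
    p: PatientRecord, quarter: Quarter, table: CodeTable, context: str = "index"
) -> TherapistCall:
    """Coding institution for the lung cancer diagnosis in *quarter*."""
    cands: set[tuple[Setting, Provider]] = set()
    for ev in p.events_in_quarter(quarter):
        if (
            ev.kind is EventKind.DIAGNOSIS
            and ev.code
            and table.has_role(CodeSystem.ICD10GM, ev.code, Role.LC_DIAGNOSIS)
        ):
            cands.add((ev.setting, ev.provider))
    if any(s is Setting.INPATIENT and pr is Provider.HOSPITAL for s, pr in cands):
        return TherapistCall(p.patient_id, context, "hospital_inpatient")
    if any(pr is Provider.HOSPITAL for _, pr in cands):
        return TherapistCall(p.patient_id, context, "hospital_outpatient")
    providers = {pr for _, pr in cands}
    for specialty in _SPECIALTY_ORDER:
        if specialty in providers:
            return TherapistCall(p.patient_id, context, "other_physician", specialty)
    return TherapistCall(p.patient_id, context, "unknown")


def _inpatient_test(p: PatientRecord, test_date: dt.date, lookback: int) -> bool:
    window_start = test_date - dt.timedelta(days=lookback)
    return any(s.overlaps(window_start, test_date) for s in p.stays)


def _detect_coded(
    p: PatientRecord,
    role: Role,
    windows: list[tuple[dt.date, dt.date]],
    table: CodeTable,
    kind: str,
    line_context: str,
    cfg: CareConfig,
) -> DiagnosticFlag:
    dates = sorted(
        ev.date
        for ev in p.events
        if ev.kind is EventKind.PROCEDURE
        and ev.code
        and ev.system
        and table.has_role(ev.system, ev.code, role)
        and any(lo <= ev.date <= hi for lo, hi in windows)
    )
    if not dates:
        return DiagnosticFlag(p.patient_id, kind, line_context)
    d = dates[0]
    setting = (
        Setting.INPATIENT
        if _inpatient_test(p, d, cfg.inpatient_lookback_days)
        else Setting.OUTPATIENT
    )
    return DiagnosticFlag(p.patient_id, kind, line_context, setting, d)


def _context_windows(
    index_q: Quarter,
    first: LineEpisode | None,
    second: LineEpisode | None,
    cfg: CareConfig,
) -> dict[str, list[tuple[dt.date, dt.date]]]:
    month = dt.timedelta(days=cfg.window_days)
    windows: dict[str, list[tuple[dt.date, dt.date]]] = {
        "first": [(index_q.start, index_q.end)]
    }
    if first is not None:
        windows["first"].append((first.start_date, first.start_date + month))
        if second is not None:
            windows["second"] = [
                (first.start_date + month + dt.timedelta(days=1), second.start_date + month)
            ]
    return windows


def detect_biomarker(
    p: PatientRecord,
    windows: list[tuple[dt.date, dt.date]],
    table: CodeTable,
    line_context: str = "first",
    cfg: CareConfig | None = None,
) -> DiagnosticFlag:
    """First biomarker test billed in *windows*, with its setting."""
    return _detect_coded(
        p, Role.BIOMARKER, windows, table, "biomarker", line_context, cfg or CareConfig()
    )


def detect_bronchoscopy(
    p: PatientRecord,
    windows: list[tuple[dt.date, dt.date]],
    table: CodeTable,
    line_context: str = "first",
    cfg: CareConfig | None = None,
) -> DiagnosticFlag:
    """First bronchoscopy billed in *windows*, with its setting."""
    return _detect_coded(
        p, Role.BRONCHOSCOPY, windows, table, "bronchoscopy", line_context, cfg or CareConfig()
    )


def detect_surgery(
    p: PatientRecord,
    index_q: Quarter,
    first: LineEpisode | None,
    table: CodeTable,
    second: LineEpisode | None = None,
    line_context: str = "first",
) -> DiagnosticFlag:
    """Surgery-role OPS in the index quarter or a line's start quarter."""
    if not table.with_role(Role.SURGERY):
        return DiagnosticFlag(p.patient_id, "surgery", line_context)
    if line_context == "first":
        quarters = {index_q}
        if first is not None:
            quarters.add(Quarter.of(first.start_date))
    else:
        quarters = {Quarter.of(second.start_date)} if second is not None else set()
    for ev in p.events:
        if (
            ev.kind is EventKind.PROCEDURE
            and ev.code
            and ev.system is CodeSystem.OPS
            and ev.quarter in quarters
            and table.has_role(ev.system, ev.code, Role.SURGERY)
        ):
            return DiagnosticFlag(
                p.patient_id, "surgery", line_context, ev.setting, ev.date
            )
    return DiagnosticFlag(p.patient_id, "surgery", line_context)


def build_care(
    records: dict[str, PatientRecord],
    selection: pd.DataFrame,
    episodes: dict[str, tuple[LineEpisode | None, LineEpisode | None]],
    table: CodeTable,
    cfg: CareConfig | None = None,
) -> pd.DataFrame:
    """Care table: therapist per context plus diagnostic flags per patient."""
    cfg = cfg or CareConfig()
    rows = []
    included = selection[selection["status"] == "included"]
    for _, row in included.iterrows():
        p = records[row["patient_id"]]
        index_q = Quarter.parse(row["index_quarter"])
        first, second = episodes.get(p.patient_id, (None, None))
        windows = _context_windows(index_q, first, second, cfg)

        therapists = {"index": attribute_therapist(p, index_q, table, "index")}
        if first is not None:
            therapists["first_line"] = attribute_therapist(
                p, Quarter.of(first.start_date), table, "first_line"
            )
        if second is not None:
            therapists["second_line"] = attribute_therapist(
                p, Quarter.of(second.start_date), table, "second_line"
            )

        for context in ("first", "second"):
            if context == "second" and "second" not in windows:
                continue
            bio = detect_biomarker(p, windows[context], table, context, cfg)
            bro = detect_bronchoscopy(p, windows[context], table, context, cfg)
            sur = detect_surgery(p, index_q, first, table, second, context)
            tcall = therapists.get(
                "index" if context == "first" else "second_line",
                therapists["index"],
            )
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "context": context,
                    "therapist": tcall.category,
                    "specialty": tcall.specialty.value if tcall.specialty else "",
                    "biomarker_setting": bio.setting.value,
                    "bronchoscopy_setting": bro.setting.value,
                    "surgery_flag": int(sur.detected),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "context",
            "therapist",
            "specialty",
            "biomarker_setting",
            "bronchoscopy_setting",
            "surgery_flag",
        ],
    )
    return df.sort_values(["patient_id", "context"], kind="stable").reset_index(drop=True)
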