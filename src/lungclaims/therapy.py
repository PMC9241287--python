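"""Treatment lines, group assignment, and drug-based NSCLC/SCLC calls.

First-line therapy is the treatment whose start is billed in the index
quarter or the following quarter; from that start, all therapy-relevant
billing (ATC dispensings plus therapy OPS/EBM items) over a one-month
window (30 days, configurable) is collected and the episode is assigned
to a treatment group by hierarchy: Immunotherapy > Inhibitors >
Chemotherapy > Radiotherapy > Study.  Scanning on from one month after
the first-line start, the first therapy code *not* billed in the
first-line window opens the second-line episode (patients may re-enter
the same group).

Cancer type is inferred from the type-specific drugs of the deciding
window: if the first-line window's typed codes are uniformly NSCLC or
uniformly SCLC, that is the call; otherwise the second line is
consulted; patients with no listed drug in any window -- or with both
types billed in the deciding window -- remain unclassifiable.

Patients without a first line fall through a rule cascade of
"other treatment" categories (no therapy documented, not observable in
line, late therapy, no follow-up diagnosis, surgery only, bronchoscopy
only, none of the above).

"Study" group items only count when a study primary code (EBM 13461 /
13492) is billed in the same quarter as one of its companion service
codes; an unpaired primary is not treatment-relevant.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .codes import (
    GROUP_PRIORITY,
    CancerType,
    CodeSystem,
    CodeTable,
    Role,
    TreatmentGroup,
)
from .model import ClaimEvent, EventKind, PatientRecord, Quarter, Setting

__all__ = [
    "TherapyConfig",
    "LineEpisode",
    "CancerTypeCall",
    "OtherCategory",
    "therapy_relevant_events",
    "detect_first_line",
    "assign_group",
    "detect_second_line",
    "classify_cancer_type",
    "categorize_untreated",
    "build_lines",
]


@dataclass(frozen=True)
class TherapyConfig:
    #: "one month" collection window, in calendar days
    window_days: int = 30


class OtherCategory(str, Enum):
    """Table-driven categories for patients without a detected line."""

    OTHER_TREATMENT = "other_treatment"
    NOT_OBSERVABLE_IN_LINE = "not_observable_in_line"
    LATE_THERAPY = "late_therapy"
    NO_FOLLOWUP_DIAGNOSIS = "no_followup_diagnosis"
    SURGERY_NO_THERAPY = "surgery_no_therapy"
    BRONCHOSCOPY_NO_SURGERY_NO_THERAPY = "bronchoscopy_no_surgery_no_therapy"
    NONE_OF_THE_ABOVE = "none_of_the_above"


@dataclass
class LineEpisode:
    patient_id: str
    line: str  # "first" | "second"
    start_date: dt.date
    window_end: dt.date
    events: list[ClaimEvent] = field(default_factory=list)
    group: TreatmentGroup = TreatmentGroup.NONE


@dataclass(frozen=True)
class CancerTypeCall:
    patient_id: str
    call: str  # "NSCLC" | "SCLC" | "unclassifiable"
    basis: str  # "first_line" | "second_line" | "none"
    conflicting: bool = False


def _study_companion_quarters(p: PatientRecord, table: CodeTable) -> set[Quarter]:
    return {
        ev.quarter
        for ev in p.events
        if ev.kind is EventKind.PROCEDURE
        and ev.code
        and ev.system
        and table.has_role(ev.system, ev.code, Role.STUDY_MARKER)
    }


def therapy_relevant_events(
    p: PatientRecord, table: CodeTable
) -> list[ClaimEvent]:
    """Events that can commence or fill a treatment line, in date order.

    ATC dispensings and OPS/EBM procedures with a therapy-role entry.
    Study primaries count only with a same-quarter companion code.
    """
    companion_q = _study_companion_quarters(p, table)
    out = []
    for ev in p.events:
        if ev.kind not in (EventKind.DISPENSING, EventKind.PROCEDURE):
            continue
        if not ev.code or not ev.system:
            continue
        group = None
        for entry in table.match(ev.system, ev.code):
            if entry.role is Role.THERAPY:
                group = entry.treatment_group
                break
        if group is None:
            continue
        if group is TreatmentGroup.STUDY and ev.quarter not in companion_q:
            continue
        out.append(ev)
    out.sort(key=lambda e: (e.date, e.system.value, e.code))
    return out


def detect_first_line(
    p: PatientRecord,
    index_q: Quarter,
    table: CodeTable,
    cfg: TherapyConfig | None = None,
) -> LineEpisode | None:
    """First-line episode, or None when no therapy starts in the index
    quarter or the quarter after."""
    cfg = cfg or TherapyConfig()
    relevant = therapy_relevant_events(p, table)
    window_quarters = (index_q, index_q.shift(1))
    starts = [ev for ev in relevant if ev.quarter in window_quarters]
    if not starts:
        return None
    start = starts[0].date
    window_end = start + dt.timedelta(days=cfg.window_days)
    episode = LineEpisode(
        patient_id=p.patient_id,
        line="first",
        start_date=start,
        window_end=window_end,
        events=[ev for ev in relevant if start <= ev.date <= window_end],
    )
    episode.group = assign_group(episode, table)
    return episode


def assign_group(episode: LineEpisode, table: CodeTable) -> TreatmentGroup:
    """Highest-priority treatment group billed in the episode window."""
    present: set[TreatmentGroup] = set()
    for ev in episode.events:
        g, _ = table.lookup_therapy(ev.code, ev.system)
        if g is not TreatmentGroup.NONE:
            present.add(g)
    for g in GROUP_PRIORITY:
        if g in present:
            return g
    return TreatmentGroup.NONE


def detect_second_line(
    p: PatientRecord,
    first: LineEpisode,
    table: CodeTable,
    cfg: TherapyConfig | None = None,
) -> LineEpisode | None:
    """Second-line episode: first therapy code after the first-line
    month that was not billed in the first-line window."""
    cfg = cfg or TherapyConfig()
    first_codes = {(ev.system, ev.code) for ev in first.events}
    cutoff = first.start_date + dt.timedelta(days=cfg.window_days)
    relevant = therapy_relevant_events(p, table)
    for ev in relevant:
        if ev.date <= cutoff:
            continue
        if (ev.system, ev.code) in first_codes:
            continue
        window_end = ev.date + dt.timedelta(days=cfg.window_days)
        episode = LineEpisode(
            patient_id=p.patient_id,
            line="second",
            start_date=ev.date,
            window_end=window_end,
            events=[e for e in relevant if ev.date <= e.date <= window_end],
        )
        episode.group = assign_group(episode, table)
        return episode
    return None


def _window_type_tags(episode: LineEpisode | None, table: CodeTable) -> set[CancerType]:
    if episode is None:
        return set()
    tags = set()
    for ev in episode.events:
        _, t = table.lookup_therapy(ev.code, ev.system)
        if t is not CancerType.NONE:
            tags.add(t)
    return tags


def classify_cancer_type(
    first: LineEpisode | None,
    second: LineEpisode | None,
    table: CodeTable,
    patient_id: str | None = None,
) -> CancerTypeCall:
    """NSCLC/SCLC call from the type-specific drugs of the line windows.

    The first-line window decides when its typed codes are uniform; an
    empty first-line tag set defers to the second line; both types in
    the deciding window -> unclassifiable with ``conflicting=True``.
    """
    if first is not None:
        pid = first.patient_id
    elif second is not None:
        pid = second.patient_id
    else:
        pid = patient_id or ""
    for episode, basis in ((first, "first_line"), (second, "second_line")):
        tags = _window_type_tags(episode, table)
        if len(tags) == 1:
            return CancerTypeCall(pid, tags.pop().value, basis)
        if len(tags) > 1:
            return CancerTypeCall(pid, "unclassifiable", basis, conflicting=True)
    return CancerTypeCall(pid, "unclassifiable", "none")


def categorize_untreated(
    p: PatientRecord,
    index_q: Quarter,
    table: CodeTable,
    surgery_flag: bool = False,
    bronchoscopy_flag: bool = False,
    cfg: TherapyConfig | None = None,
) -> OtherCategory:
    """Rule cascade for included patients without a first-line episode.

    Evaluated in order; the first matching rule wins:

    1. other_treatment -- nonspecific inpatient treatment (OPS 8-541)
       within one month after the index quarter;
    2. not_observable_in_line -- no billing of any kind after the index
       quarter (no follow-up documentation);
    3. late_therapy -- therapy billed, but only after the line windows;
    4. no_followup_diagnosis -- lung cancer never re-coded after the
       index quarter;
    5. surgery_no_therapy -- surgery billed in the observation phase;
    6. bronchoscopy_no_surgery_no_therapy -- bronchoscopy billed;
    7. none_of_the_above.
    """
    cfg = cfg or TherapyConfig()
    index_end = index_q.end
    marker_deadline = index_end + dt.timedelta(days=cfg.window_days)

    has_marker = any(
        ev.kind is EventKind.PROCEDURE
        and ev.code
        and ev.system
        and table.has_role(ev.system, ev.code, Role.INPATIENT_CHEMO_MARKER)
        and index_q.start <= ev.date <= marker_deadline
        for ev in p.events
    )
    if has_marker:
        return OtherCategory.OTHER_TREATMENT

    if not any(ev.date > index_end for ev in p.events):
        return OtherCategory.NOT_OBSERVABLE_IN_LINE

    relevant = therapy_relevant_events(p, table)
    line_window_end = index_q.shift(1).end
    if any(ev.date > line_window_end for ev in relevant):
        return OtherCategory.LATE_THERAPY

    lc_recoded = any(
        ev.kind is EventKind.DIAGNOSIS
        and ev.code
        and table.has_role(CodeSystem.ICD10GM, ev.code, Role.LC_DIAGNOSIS)
        and ev.quarter > index_q
        for ev in p.events
    )
    if not lc_recoded:
        return OtherCategory.NO_FOLLOWUP_DIAGNOSIS

    if surgery_flag:
        return OtherCategory.SURGERY_NO_THERAPY
    if bronchoscopy_flag:
        return OtherCategory.BRONCHOSCOPY_NO_SURGERY_NO_THERAPY
    return OtherCategory.NONE_OF_THE_ABOVE


def build_lines(
    records: dict[str, PatientRecord],
    selection: pd.DataFrame,
    table: CodeTable,
    cfg: TherapyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[LineEpisode | None, LineEpisode | None]]]:
    """Line episodes and cancer-type calls for every included patient.

    Returns (lines, types, episodes) where *lines* has one row per
    detected episode, *types* one row per included patient, and
    *episodes* maps patient id to its (first, second) episode pair for
    downstream modules.
    """
    cfg = cfg or TherapyConfig()
    line_rows, type_rows = [], []
    episodes: dict[str, tuple[LineEpisode | None, LineEpisode | None]] = {}
    included = selection[selection["status"] == "included"]
    for _, row in included.iterrows():
        p = records[row["patient_id"]]
        index_q = Quarter.parse(row["index_quarter"])
        first = detect_first_line(p, index_q, table, cfg)
        second = detect_second_line(p, first, table, cfg) if first else None
        episodes[p.patient_id] = (first, second)
        for ep in (first, second):
            if ep is not None:
                line_rows.append(
                    {
                        "patient_id": ep.patient_id,
                        "line": ep.line,
                        "start": ep.start_date.isoformat(),
                        "window_end": ep.window_end.isoformat(),
                        "group": ep.group.value,
                    }
                )
        call = classify_cancer_type(first, second, table, patient_id=p.patient_id)
        type_rows.append(
            {
                "patient_id": call.patient_id,
                "call": call.call,
                "basis": call.basis,
                "conflicting": int(call.conflicting),
            }
        )
    lines = pd.DataFrame(line_rows, columns=["patient_id", "line", "start", "window_end", "group"])
    types = pd.DataFrame(type_rows, columns=["patient_id", "call", "basis", "conflicting"])
    return (
        lines.sort_values(["patient_id", "line"], kind="stable").reset_index(drop=True),
        types.sort_values("patient_id", kind="stable").reset_index(drop=True),
        episodes,
    )
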