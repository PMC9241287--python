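"""Incident-cohort selection: index quarter, confirmation, exclusions, stage.

The selection algorithm identifies incident lung cancer cases in a
claims extract:

1. *Index quarter*: the earliest quarter in the study period (2015-2016
   by default) containing a C33/C34 diagnosis.
2. *Confirmation*: the diagnosis counts as valid if it was coded in the
   outpatient setting in at least two different quarters of the
   observation period (the M2Q criterion) or once as a confirmed
   inpatient diagnosis.
3. *Washout*: no C33/C34 in the eight quarters before the index quarter
   (incidence, not prevalence).
4. *Exclusions*: insufficient pre-/post-observation enrollment and any
   further primary solid tumor (C00-C75 except C33, C34, C44, C61)
   within eight quarters of the index quarter.

A patient failing several checks receives exactly one exclusion reason:
the first failing check in the fixed order confirmation -> washout ->
pre-observation -> other-primary -> post-observation, so exclusion
counts partition the candidate pool.

Included patients are staged from metastasis codes in the index quarter
(C78/C79 -> distant, else C77 -> lymph node, else no metastases; distant
dominates when codes co-occur) and stratified by age at index (<=60 vs
>60), gender, and urban/rural residence.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .codes import CodeSystem, CodeTable, Role, load_default_table
from .model import EventKind, PatientRecord, Quarter, Setting

__all__ = [
    "Stage",
    "ExclusionReason",
    "CohortConfig",
    "SelectionResult",
    "find_index_quarter",
    "is_newly_diagnosed",
    "confirm_diagnosis",
    "outpatient_m2q",
    "is_other_primary_code",
    "apply_exclusions",
    "assign_stage",
    "stratify_demographics",
    "select_cohort",
]


class Stage(str, Enum):
    NO_METS = "no_mets"
    LYMPH_NODE_METS = "lymph_node_mets"
    DISTANT_METS = "distant_mets"


class ExclusionReason(str, Enum):
    NOT_CONFIRMED = "not_confirmed"
    PRIOR_LC_DIAGNOSIS = "prior_lc_diagnosis"
    INSUFFICIENT_PRE_OBSERVATION = "insufficient_pre_observation"
    OTHER_PRIMARY_TUMOR = "other_primary_tumor"
    INSUFFICIENT_POST_OBSERVATION = "insufficient_post_observation"
    NONE = "none"


#: Exclusion checks run in this order; the first failure is recorded.
EXCLUSION_ORDER: tuple[ExclusionReason, ...] = (
    ExclusionReason.NOT_CONFIRMED,
    ExclusionReason.PRIOR_LC_DIAGNOSIS,
    ExclusionReason.INSUFFICIENT_PRE_OBSERVATION,
    ExclusionReason.OTHER_PRIMARY_TUMOR,
    ExclusionReason.INSUFFICIENT_POST_OBSERVATION,
)


@dataclass(frozen=True)
class CohortConfig:
    """Tunable parameters of the selection algorithm."""

    period_start: dt.date = dt.date(2015, 1, 1)
    period_end: dt.date = dt.date(2016, 12, 31)
    #: end of the data horizon; M2Q confirmation may use outpatient
    #: diagnoses up to here (treatment follow-up extends beyond the
    #: index period)
    observation_end: dt.date = dt.date(2018, 12, 31)
    washout_quarters: int = 8
    pre_observation_quarters: int = 8
    other_primary_window_quarters: int = 8


@dataclass(frozen=True)
class SelectionResult:
    patient_id: str
    status: str  # "included" | "excluded"
    exclusion_reason: ExclusionReason
    index_quarter: Quarter | None
    stage: Stage | None = None
    age_group: str | None = None
    gender: str | None = None
    region: str | None = None


def _lc_diagnosis_events(p: PatientRecord, table: CodeTable):
    for ev in p.events:
        if (
            ev.kind is EventKind.DIAGNOSIS
            and ev.code
            and table.has_role(CodeSystem.ICD10GM, ev.code, Role.LC_DIAGNOSIS)
        ):
            yield ev


def find_index_quarter(
    p: PatientRecord, cfg: CohortConfig, table: CodeTable
) -> Quarter | None:
    """Earliest quarter within the study period with a C33/C34 diagnosis."""
    quarters = [
        ev.quarter
        for ev in _lc_diagnosis_events(p, table)
        if cfg.period_start <= ev.date <= cfg.period_end
    ]
    return min(quarters) if quarters else None


def is_newly_diagnosed(
    p: PatientRecord, index_q: Quarter, table: CodeTable, washout_quarters: int = 8
) -> bool:
    """No C33/C34 diagnosis in the ``washout_quarters`` before the index."""
    lo, hi = index_q.shift(-washout_quarters), index_q.shift(-1)
    return not any(
        lo <= ev.quarter <= hi for ev in _lc_diagnosis_events(p, table)
    )


def outpatient_m2q(
    p: PatientRecord, cfg: CohortConfig, table: CodeTable
) -> bool:
    """Outpatient C33/C34 coded in >= 2 different quarters of the
    observation period (all outpatient diagnoses count, regardless of
    certainty marker)."""
    quarters = {
        ev.quarter
        for ev in _lc_diagnosis_events(p, table)
        if ev.setting is Setting.OUTPATIENT and ev.date <= cfg.observation_end
    }
    return len(quarters) >= 2


def confirm_diagnosis(
    p: PatientRecord, index_q: Quarter, cfg: CohortConfig, table: CodeTable
) -> bool:
    """M2Q criterion, or one confirmed inpatient C33/C34 diagnosis."""
    if outpatient_m2q(p, cfg, table):
        return True
    return any(
        ev.setting is Setting.INPATIENT and ev.confirmed and ev.date <= cfg.observation_end
        for ev in _lc_diagnosis_events(p, table)
    )


#: ICD-10 3-character prefixes exempt from the other-primary-tumor rule.
_OTHER_PRIMARY_EXEMPT = ("C33", "C34", "C44", "C61")


def is_other_primary_code(code: str) -> bool:
    """Is *code* a further primary solid tumor (C00-C75 without C33, C34,
    C44, C61)?  Codes are canonical (no dots)."""
    if len(code) < 3 or code[0] != "C" or not code[1:3].isdigit():
        return False
    if any(code.startswith(x) for x in _OTHER_PRIMARY_EXEMPT):
        return False
    return 0 <= int(code[1:3]) <= 75


def _has_other_primary(p: PatientRecord, index_q: Quarter, window: int) -> bool:
    lo, hi = index_q.shift(-window), index_q.shift(window)
    return any(
        ev.kind is EventKind.DIAGNOSIS
        and ev.code
        and is_other_primary_code(ev.code)
        and lo <= ev.quarter <= hi
        for ev in p.events
    )


def _has_pre_observation(p: PatientRecord, index_q: Quarter, quarters: int) -> bool:
    return p.enrollment_covers(index_q.shift(-quarters).start, index_q.start - dt.timedelta(days=1))


def _has_post_observation(p: PatientRecord, index_q: Quarter) -> bool:
    # enrollment must reach into the quarter following the index quarter
    end = p.enrollment_end
    return end is not None and end >= index_q.shift(1).start


def apply_exclusions(
    p: PatientRecord, index_q: Quarter, cfg: CohortConfig, table: CodeTable
) -> SelectionResult:
    """Run the exclusion cascade; first failing check wins."""
    checks = {
        ExclusionReason.NOT_CONFIRMED: lambda: confirm_diagnosis(p, index_q, cfg, table),
        ExclusionReason.PRIOR_LC_DIAGNOSIS: lambda: is_newly_diagnosed(
            p, index_q, table, cfg.washout_quarters
        ),
        ExclusionReason.INSUFFICIENT_PRE_OBSERVATION: lambda: _has_pre_observation(
            p, index_q, cfg.pre_observation_quarters
        ),
        ExclusionReason.OTHER_PRIMARY_TUMOR: lambda: not _has_other_primary(
            p, index_q, cfg.other_primary_window_quarters
        ),
        ExclusionReason.INSUFFICIENT_POST_OBSERVATION: lambda: _has_post_observation(
            p, index_q
        ),
    }
    for reason in EXCLUSION_ORDER:
        if not checks[reason]():
            return SelectionResult(p.patient_id, "excluded", reason, index_q)
    return SelectionResult(p.patient_id, "included", ExclusionReason.NONE, index_q)


def assign_stage(p: PatientRecord, index_q: Quarter, table: CodeTable) -> Stage:
    """Stage from metastasis codes in the index quarter; distant > lymph."""
    roles: set[Role] = set()
    for ev in p.events_in_quarter(index_q):
        if ev.kind is EventKind.DIAGNOSIS and ev.code:
            roles |= table.roles(CodeSystem.ICD10GM, ev.code)
    if Role.DISTANT_MET in roles:
        return Stage.DISTANT_METS
    if Role.LYMPH_MET in roles:
        return Stage.LYMPH_NODE_METS
    return Stage.NO_METS


def stratify_demographics(
    p: PatientRecord, index_q: Quarter
) -> tuple[str, str, str]:
    """(age_group, gender, region) at the index quarter.

    Age = index year - birth year, grouped <=60 vs >60; a missing birth
    year yields ``unknown`` (reported, never dropped).
    """
    if p.birth_year is None:
        age_group = "unknown"
    else:
        age = index_q.year - p.birth_year
        age_group = "<=60" if age <= 60 else ">60"
    return age_group, p.gender.value, p.municipality.value


def select_cohort(
    records: list[PatientRecord],
    cfg: CohortConfig | None = None,
    table: CodeTable | None = None,
) -> pd.DataFrame:
    """Selection table over all candidates (patients with an index quarter).

    Columns: patient_id, status, exclusion_reason, index_quarter, stage,
    age_group, gender, region.  Stage and strata are filled for included
    patients only.
    """
    cfg = cfg or CohortConfig()
    table = table or load_default_table()
    rows = []
    for p in records:
        index_q = find_index_quarter(p, cfg, table)
        if index_q is None:
            continue
        res = apply_exclusions(p, index_q, cfg, table)
        if res.status == "included":
            stage = assign_stage(p, index_q, table)
            age_group, gender, region = stratify_demographics(p, index_q)
        else:
            stage, age_group, gender, region = None, None, None, None
        rows.append(
            {
                "patient_id": p.patient_id,
                "status": res.status,
                "exclusion_reason": res.exclusion_reason.value,
                "index_quarter": str(index_q),
                "stage": stage.value if stage else "",
                "age_group": age_group or "",
                "gender": gender or "",
                "region": region or "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "status",
            "exclusion_reason",
            "index_quarter",
            "stage",
            "age_group",
            "gender",
            "region",
        ],
    )
    return df.sort_values("patient_id", kind="stable").reset_index(drop=True)
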