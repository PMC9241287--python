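"""Synthetic SHI-like claims populations with ground-truth labels.

Real German SHI billing extracts are proprietary, so every pipeline
stage is exercised against generated populations that emulate the
structural features the selection and therapy rules key on:
quarter-resolved diagnosis coding, confirmation either by outpatient
coding in two quarters (M2Q) or by a confirmed inpatient diagnosis,
metastasis codes in the index quarter, therapy events timed relative to
the index quarter with Table-style drug/procedure codes, planned
exclusion contamination (other primary tumors, truncated enrollment),
and demographic strata.

Every patient draws from an independent pseudo-random stream derived
from ``(seed, patient index)``, so populations are reproducible and
stable under subsetting.  :class:`TruthRecord` carries the generating
labels (incidence, type, stage, line groups, planned exclusion), which
recovery tests compare against pipeline output.

The generator emulates structure, not InGef marginals: no comorbidity
correlation, no cost fields, and therapy timing within a window is a
fixed grid (0/7/14/21 days) because the source rules constrain windows,
not intra-window timing.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .codes import (
    CancerType,
    CodeEntry,
    CodeSystem,
    CodeTable,
    Role,
    TreatmentGroup,
    load_default_table,
)
from .model import (
    ClaimEvent,
    EventKind,
    Gender,
    HospitalStay,
    PatientRecord,
    Provider,
    Quarter,
    Region,
    Setting,
    StayMode,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioError",
    "TruthRecord",
    "generate_population",
    "inject_edge_cases",
    "edge_case_panel",
    "write_truth",
    "read_truth",
]


class ScenarioError(ValueError):
    """Infeasible or inconsistent scenario configuration."""


_GROUPS = ["Immunotherapy", "Inhibitors", "Chemotherapy", "Radiotherapy", "Study"]
_STAGES = ["no_mets", "lymph_node", "distant"]
_EXCLUSIONS = ["other_primary", "short_pre_observation", "short_post_observation"]
_OTHER_CATS = [
    "other_treatment",
    "not_observable_in_line",
    "late_therapy",
    "no_followup_diagnosis",
    "surgery_no_therapy",
    "bronchoscopy_no_surgery_no_therapy",
    "none_of_the_above",
]


class ScenarioConfig(BaseModel):
    """Study conditions of a generated population.

    Defaults mirror the structure of the source study population: an
    80:20 NSCLC:SCLC split, roughly 62% of incident patients with a
    treatment start in the line window, chemotherapy-dominated group
    mix, exclusion contamination of ~31% other primary tumors and
    4%/10.5% insufficient pre-/post-observation, mostly-inpatient
    initial coding, and a 79% urban population.
    """

    n_patients: int = Field(default=1000, ge=0)
    seed: int = 0
    lc_fraction: float = 0.5
    type_mixture: tuple[float, float] = (0.8, 0.2)  # (NSCLC, SCLC)
    stage_mixture: dict[str, float] = Field(
        default_factory=lambda: {"no_mets": 0.35, "lymph_node": 0.15, "distant": 0.50}
    )
    treated_fraction: float = 0.62
    group_mixture: dict[str, float] = Field(
        default_factory=lambda: {
            "Immunotherapy": 0.10,
            "Inhibitors": 0.06,
            "Chemotherapy": 0.65,
            "Radiotherapy": 0.16,
            "Study": 0.03,
        }
    )
    #: probability that a treated patient's line drugs contradict the
    #: true cancer type (off-label use)
    off_label_rate: float = 0.2
    #: force every drawn drug to carry the patient's true type
    #: (classifiable-by-construction scenarios)
    type_specific_only: bool = False
    exclusion_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "other_primary": 0.309,
            "short_pre_observation": 0.040,
            "short_post_observation": 0.105,
        }
    )
    #: probability that diagnosis confirmation happens via outpatient
    #: coding in two quarters rather than one confirmed inpatient coding
    m2q_fraction: float = 0.2
    second_line_fraction: float = 0.3
    urban_fraction: float = 0.79
    age_young_fraction: float = 0.25
    age_young_range: tuple[int, int] = (35, 60)
    age_old_range: tuple[int, int] = (61, 88)
    index_period_start: dt.date = dt.date(2015, 1, 1)
    index_period_end: dt.date = dt.date(2016, 12, 31)
    data_start: dt.date = dt.date(2013, 1, 1)
    data_end: dt.date = dt.date(2018, 12, 31)
    # per-quarter contact intensities (Poisson means)
    gp_visit_rate: float = 1.0
    specialist_visit_rate_pre: float = 0.4
    specialist_visit_rate_post: float = 3.0
    hospital_outpatient_rate: float = 0.8
    chronic_rx_rate: float = 0.7
    followup_dx_rate: float = 0.6

    @field_validator(
        "lc_fraction",
        "treated_fraction",
        "off_label_rate",
        "m2q_fraction",
        "second_line_fraction",
        "urban_fraction",
        "age_young_fraction",
        "followup_dx_rate",
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {v}")
        return v

    @model_validator(mode="after")
    def _mixtures(self) -> "ScenarioConfig":
        if abs(sum(self.type_mixture) - 1.0) > 1e-6:
            raise ValueError("type_mixture must sum to 1")
        if any(p < 0 for p in self.type_mixture):
            raise ValueError("type_mixture must be non-negative")
        for name, mix, keys in (
            ("stage_mixture", self.stage_mixture, _STAGES),
            ("group_mixture", self.group_mixture, _GROUPS),
        ):
            if set(mix) - set(keys):
                raise ValueError(f"{name}: unknown keys {set(mix) - set(keys)}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} must be non-negative")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if set(self.exclusion_rates) - set(_EXCLUSIONS):
            raise ValueError(f"unknown exclusion kinds {set(self.exclusion_rates) - set(_EXCLUSIONS)}")
        if sum(self.exclusion_rates.values()) > 1.0 + 1e-9:
            raise ValueError("exclusion_rates must sum to at most 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class TruthRecord:
    """Generating labels of one synthetic patient."""

    patient_id: str
    is_incident_lc: bool
    true_type: str = "none"  # NSCLC | SCLC | none
    true_stage: str = ""  # no_mets | lymph_node | distant | ""
    true_index_quarter: str = ""  # e.g. "2015Q3"
    true_first_line_group: str = "none"
    true_second_line_group: str = "none"
    planned_exclusion_reason: str = "none"
    true_other_category: str = "none"


# --------------------------------------------------------------------------
# drug pools


def _therapy_pools(table: CodeTable) -> dict[str, dict[str, list[CodeEntry]]]:
    """ATC therapy entries per group, split by cancer-type tag."""
    pools: dict[str, dict[str, list[CodeEntry]]] = {
        g: {"NSCLC": [], "SCLC": [], "none": []} for g in _GROUPS
    }
    for e in table.with_role(Role.THERAPY):
        if e.system is not CodeSystem.ATC:
            continue
        g = e.treatment_group.value
        if g in pools:
            pools[g][e.cancer_type.value].append(e)
    for g in pools:
        for k in pools[g]:
            pools[g][k].sort(key=lambda e: e.code)
    return pools


def _validate_feasibility(cfg: ScenarioConfig, pools) -> None:
    if not (cfg.type_specific_only or cfg.off_label_rate == 0.0):
        return
    drug_groups = ("Immunotherapy", "Inhibitors", "Chemotherapy")
    for ti, tname in enumerate(("NSCLC", "SCLC")):
        if cfg.type_mixture[ti] <= 0:
            continue
        for g, mass in cfg.group_mixture.items():
            if mass <= 0 or g not in drug_groups:
                if mass > 0 and cfg.type_specific_only and g not in drug_groups:
                    raise ScenarioError(
                        f"type_specific_only: group {g} has no type-specific drugs"
                    )
                continue
            same = pools[g][tname]
            untyped = pools[g]["none"]
            if cfg.type_specific_only and not same:
                raise ScenarioError(
                    f"infeasible mixture: no {tname}-specific drug in group {g}"
                )
            if cfg.off_label_rate == 0.0 and not (same or untyped):
                raise ScenarioError(
                    f"infeasible mixture: group {g} incompatible with true type {tname}"
                )


# --------------------------------------------------------------------------
# small sampling helpers


def _rand_date(rng, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _distinct_days(rng, start: dt.date, end: dt.date, n: int) -> list[dt.date]:
    span = (end - start).days + 1
    n = min(n, span)
    if n <= 0:
        return []
    offs = rng.choice(span, size=n, replace=False)
    return sorted(start + dt.timedelta(days=int(o)) for o in offs)


def _pick(rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _weighted(rng, items: list[str], weights: list[float]) -> str:
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if u < acc:
            return item
    return items[-1]


_LC_CODES = ["C34", "C340", "C341", "C343", "C349", "C33"]
_OTHER_PRIMARY_CODES = ["C50", "C18", "C64", "C16"]
_BENIGN_CODES = ["J44", "I10", "E11", "M54"]
_CHRONIC_ATC = ["C07AB02", "A10BA02", "C10AA01"]
_BRONCH_CODES = [("OPS", "1-620"), ("OPS", "1-6900")]
_BIOMARKER_CODES = [("EBM", "19320"), ("EBM", "19321"), ("EBM", "19322")]
_SURGERY_CODES = ["5-324", "5-328", "5-335"]


def _choose_drug(pools, group: str, true_type: str, contradict: bool,
                 type_specific_only: bool, rng, exclude: set[str] = frozenset()):
    """Pick an ATC entry for a drug group honoring type constraints."""
    other = "SCLC" if true_type == "NSCLC" else "NSCLC"
    same = [e for e in pools[group][true_type] if e.code not in exclude]
    untyped = [e for e in pools[group]["none"] if e.code not in exclude]
    wrong = [e for e in pools[group][other] if e.code not in exclude]
    if type_specific_only:
        order = [same]
    elif contradict:
        order = [wrong, untyped, same]
    else:
        order = [same, untyped, wrong]
    for pool in order:
        if pool:
            return _pick(rng, pool)
    return None


# --------------------------------------------------------------------------
# per-patient generation


def _gen_incident(
    pid: str, rng, cfg: ScenarioConfig, pools, quarters: list[Quarter]
) -> tuple[PatientRecord, TruthRecord]:
    p = PatientRecord(patient_id=pid)
    ev = p.events.append
    index_q = quarters[int(rng.integers(0, len(quarters)))]
    dx_date = _rand_date(rng, index_q.start, index_q.end)

    # planned exclusion -------------------------------------------------
    u = rng.random()
    planned = "none"
    acc = 0.0
    for kind in _EXCLUSIONS:
        acc += cfg.exclusion_rates.get(kind, 0.0)
        if u < acc:
            planned = kind
            break

    enroll_start, enroll_end = cfg.data_start, cfg.data_end
    if planned == "short_pre_observation":
        k = int(rng.integers(1, 8))  # 1..7 quarters of pre-observation
        enroll_start = index_q.shift(-k).start
    elif planned == "short_post_observation":
        enroll_end = index_q.end
    p.enrollment.append((enroll_start, enroll_end))

    # demographics ------------------------------------------------------
    young = rng.random() < cfg.age_young_fraction
    lo, hi = cfg.age_young_range if young else cfg.age_old_range
    age = int(rng.integers(lo, hi + 1))
    p.birth_year = index_q.year - age
    p.gender = Gender.MALE if rng.random() < 0.63 else Gender.FEMALE
    p.municipality = Region.URBAN if rng.random() < cfg.urban_fraction else Region.RURAL

    # type / stage / treatment plan ------------------------------------
    true_type = "NSCLC" if rng.random() < cfg.type_mixture[0] else "SCLC"
    stage = _weighted(rng, _STAGES, [cfg.stage_mixture.get(s, 0.0) for s in _STAGES])
    treated = rng.random() < cfg.treated_fraction
    other_cat = "none"
    if not treated:
        other_cat = _weighted(
            rng, _OTHER_CATS, [0.10, 0.15, 0.10, 0.15, 0.15, 0.15, 0.20]
        )
    no_post_events = other_cat == "not_observable_in_line"
    no_followup_dx = other_cat in ("not_observable_in_line", "no_followup_diagnosis")

    # confirmation route ------------------------------------------------
    force_inpatient = planned == "short_post_observation" or no_post_events or no_followup_dx
    route_m2q = (not force_inpatient) and rng.random() < cfg.m2q_fraction
    outpatient_provider = _pick(
        rng, [Provider.PULMONOLOGIST, Provider.PRIMARY_CARE, Provider.INTERNIST]
    )
    lc_code = _pick(rng, _LC_CODES)
    if route_m2q:
        ev(
            ClaimEvent(pid, dx_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, lc_code,
                       Setting.OUTPATIENT, outpatient_provider, confirmed=bool(rng.random() < 0.5))
        )
        confirm_q = index_q.shift(int(rng.integers(1, 3)))
        confirm_date = _rand_date(rng, confirm_q.start, min(confirm_q.end, enroll_end))
        ev(
            ClaimEvent(pid, confirm_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                       _pick(rng, _LC_CODES), Setting.OUTPATIENT, outpatient_provider,
                       confirmed=True)
        )
    else:
        ev(
            ClaimEvent(pid, dx_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, lc_code,
                       Setting.INPATIENT, Provider.HOSPITAL, confirmed=True)
        )
        discharge = min(dx_date + dt.timedelta(days=int(rng.integers(3, 13))), enroll_end)
        p.stays.append(HospitalStay(pid, dx_date, discharge, StayMode.INPATIENT))

    # stage codes in the index quarter ---------------------------------
    if stage == "lymph_node":
        ev(ClaimEvent(pid, dx_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                      _pick(rng, ["C77", "C770", "C773"]),
                      Setting.INPATIENT if not route_m2q else Setting.OUTPATIENT,
                      Provider.HOSPITAL if not route_m2q else outpatient_provider))
    elif stage == "distant":
        ev(ClaimEvent(pid, dx_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                      _pick(rng, ["C78", "C780", "C787", "C79", "C793"]),
                      Setting.INPATIENT if not route_m2q else Setting.OUTPATIENT,
                      Provider.HOSPITAL if not route_m2q else outpatient_provider))
        if rng.random() < 0.5:
            ev(ClaimEvent(pid, dx_date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, "C77",
                          Setting.INPATIENT if not route_m2q else Setting.OUTPATIENT,
                          Provider.HOSPITAL if not route_m2q else outpatient_provider))

    # planned other-primary contamination ------------------------------
    if planned == "other_primary":
        offset = int(rng.integers(-4, 5))
        oq = index_q.shift(offset)
        od = _rand_date(rng, max(oq.start, enroll_start), min(oq.end, enroll_end))
        ev(ClaimEvent(pid, od, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                      _pick(rng, _OTHER_PRIMARY_CODES), Setting.OUTPATIENT,
                      Provider.OTHER_OFFICE_BASED))

    # follow-up LC coding ----------------------------------------------
    followups: list[Quarter] = []
    if not no_followup_dx:
        for r in range(1, 7):
            q = index_q.shift(r)
            if q.start > enroll_end:
                break
            if rng.random() < cfg.followup_dx_rate:
                followups.append(q)
        if other_cat in (
            "surgery_no_therapy",
            "bronchoscopy_no_surgery_no_therapy",
            "none_of_the_above",
            "late_therapy",
            "other_treatment",
        ) and not followups and index_q.shift(1).start <= enroll_end:
            followups.append(index_q.shift(1))
        for q in followups:
            fd = _rand_date(rng, q.start, min(q.end, enroll_end))
            ev(ClaimEvent(pid, fd, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                          _pick(rng, _LC_CODES), Setting.OUTPATIENT,
                          outpatient_provider, confirmed=True))

    # therapy ----------------------------------------------------------
    fl_group, sl_group = "none", "none"
    contradict = (not cfg.type_specific_only) and rng.random() < cfg.off_label_rate
    if treated:
        fl_group = _weighted(rng, _GROUPS, [cfg.group_mixture.get(g, 0.0) for g in _GROUPS])
        fl_end_limit = index_q.shift(1).end if planned != "short_post_observation" else index_q.end
        fl_start = _rand_date(rng, index_q.start, fl_end_limit)
        fl_codes = _emit_line_events(
            p, rng, cfg, pools, fl_group, true_type, contradict, fl_start, n_days=(0, 7, 14, 21)
        )
        if rng.random() < cfg.second_line_fraction and planned != "short_post_observation":
            sl_start = fl_start + dt.timedelta(days=35 + int(rng.integers(0, 56)))
            if sl_start <= min(enroll_end, cfg.data_end):
                for _ in range(10):
                    g2 = _weighted(rng, _GROUPS, [cfg.group_mixture.get(g, 0.0) for g in _GROUPS])
                    codes2 = _emit_line_events(
                        p, rng, cfg, pools, g2, true_type, contradict, sl_start,
                        n_days=(0, 7), exclude=fl_codes, dry_check=True,
                    )
                    if codes2:
                        sl_group = g2
                        break

        # diagnostics for treated patients
        if rng.random() < 0.8:
            sys_, code = _pick(rng, _BRONCH_CODES)
            bd = min(dx_date + dt.timedelta(days=int(rng.integers(0, 10))), index_q.end)
            ev(ClaimEvent(pid, bd, EventKind.PROCEDURE, CodeSystem(sys_), code,
                          Setting.INPATIENT, Provider.HOSPITAL))
        if rng.random() < 0.11:
            sys_, code = _pick(rng, _BIOMARKER_CODES)
            td = min(dx_date + dt.timedelta(days=int(rng.integers(0, 15))), index_q.end)
            ev(ClaimEvent(pid, td, EventKind.PROCEDURE, CodeSystem(sys_), code,
                          Setting.OUTPATIENT, Provider.ONCOLOGIST))
    else:
        _emit_untreated_extras(p, rng, index_q, other_cat, pools, true_type, contradict, enroll_end)

    # background contacts and chronic dispensings ----------------------
    _emit_contacts(p, rng, cfg, index_q, treated, no_post_events, enroll_start, enroll_end)

    truth = TruthRecord(
        patient_id=pid,
        is_incident_lc=True,
        true_type=true_type,
        true_stage=stage,
        true_index_quarter=str(index_q),
        true_first_line_group=fl_group,
        true_second_line_group=sl_group,
        planned_exclusion_reason=planned,
        true_other_category=other_cat,
    )
    return p.sort().flag_enrollment(), truth


def _emit_line_events(
    p, rng, cfg, pools, group, true_type, contradict, start, n_days,
    exclude: set[str] = frozenset(), dry_check: bool = False,
) -> set[str]:
    """Emit the billing of one treatment-line window; returns codes used.

    With ``dry_check`` nothing is emitted unless a usable code exists,
    so second-line sampling can retry with a different group.
    """
    pid = p.patient_id
    emitted: set[str] = set()
    if group in ("Immunotherapy", "Inhibitors", "Chemotherapy"):
        entry = _choose_drug(pools, group, true_type, contradict, cfg.type_specific_only, rng, exclude)
        if entry is None:
            return set()
        for i, d in enumerate(n_days):
            if i > 0 and rng.random() > 0.7:
                continue
            p.events.append(
                ClaimEvent(pid, start + dt.timedelta(days=d), EventKind.DISPENSING,
                           CodeSystem.ATC, entry.code, Setting.NONE, Provider.PHARMACY)
            )
        emitted.add(entry.code)
        # platinum backbone: an untyped companion drug, when allowed
        if (
            group == "Chemotherapy"
            and not cfg.type_specific_only
            and rng.random() < 0.4
        ):
            comp = [e for e in pools["Chemotherapy"]["none"] if e.code not in exclude | emitted]
            if comp:
                c = _pick(rng, comp)
                p.events.append(
                    ClaimEvent(pid, start, EventKind.DISPENSING, CodeSystem.ATC,
                               c.code, Setting.NONE, Provider.PHARMACY)
                )
                emitted.add(c.code)
    elif group == "Radiotherapy":
        code = _pick(rng, ["25320", "25321", "25322", "8-522"])
        if code in exclude:
            code = "25323"
        if code.startswith("8-"):
            p.events.append(
                ClaimEvent(pid, start, EventKind.PROCEDURE, CodeSystem.OPS, code,
                           Setting.INPATIENT, Provider.HOSPITAL)
            )
        else:
            for d in n_days[:2]:
                p.events.append(
                    ClaimEvent(pid, start + dt.timedelta(days=d), EventKind.PROCEDURE,
                               CodeSystem.EBM, code, Setting.OUTPATIENT, Provider.RADIOLOGIST)
                )
        emitted.add(code)
    elif group == "Study":
        primary = _pick(rng, ["13461", "13492"])
        if primary in exclude:
            primary = "13492" if primary == "13461" else "13461"
            if primary in exclude:
                return set()
        companion = _pick(rng, ["02100", "02101", "01510"])
        p.events.append(
            ClaimEvent(pid, start, EventKind.PROCEDURE, CodeSystem.EBM, primary,
                       Setting.OUTPATIENT, Provider.ONCOLOGIST)
        )
        p.events.append(
            ClaimEvent(pid, start, EventKind.PROCEDURE, CodeSystem.EBM, companion,
                       Setting.OUTPATIENT, Provider.ONCOLOGIST)
        )
        emitted.add(primary)
    return emitted


def _emit_untreated_extras(p, rng, index_q, other_cat, pools, true_type, contradict, enroll_end):
    pid = p.patient_id
    if other_cat == "other_treatment":
        d = index_q.end + dt.timedelta(days=int(rng.integers(1, 31)))
        p.events.append(
            ClaimEvent(pid, min(d, enroll_end), EventKind.PROCEDURE, CodeSystem.OPS,
                       "8-541", Setting.INPATIENT, Provider.HOSPITAL)
        )
    elif other_cat == "late_therapy":
        q = index_q.shift(int(rng.integers(2, 5)))
        if q.start <= enroll_end:
            d = _rand_date(rng, q.start, min(q.end, enroll_end))
            entry = _choose_drug(pools, "Chemotherapy", true_type, contradict, False, rng)
            if entry is not None:
                p.events.append(
                    ClaimEvent(pid, d, EventKind.DISPENSING, CodeSystem.ATC,
                               entry.code, Setting.NONE, Provider.PHARMACY)
                )
    elif other_cat == "surgery_no_therapy":
        d = _rand_date(rng, index_q.start, index_q.end)
        p.events.append(
            ClaimEvent(pid, d, EventKind.PROCEDURE, CodeSystem.OPS,
                       _pick(rng, _SURGERY_CODES), Setting.INPATIENT, Provider.HOSPITAL)
        )
    elif other_cat == "bronchoscopy_no_surgery_no_therapy":
        sys_, code = _pick(rng, _BRONCH_CODES)
        d = _rand_date(rng, index_q.start, index_q.end)
        p.events.append(
            ClaimEvent(pid, d, EventKind.PROCEDURE, CodeSystem(sys_), code,
                       Setting.INPATIENT, Provider.HOSPITAL)
        )


def _emit_contacts(p, rng, cfg, index_q, treated, no_post_events, enroll_start, enroll_end):
    pid = p.patient_id
    for r in range(-4, 9):
        q = index_q.shift(r)
        lo, hi = max(q.start, enroll_start), min(q.end, enroll_end)
        if lo > hi:
            continue
        if no_post_events and r > 0:
            continue
        if no_post_events and r == 0:
            hi = min(hi, index_q.end)
        n_gp = int(rng.poisson(cfg.gp_visit_rate))
        for d in _distinct_days(rng, lo, hi, n_gp):
            p.events.append(
                ClaimEvent(pid, d, EventKind.CONTACT, None, None,
                           Setting.OUTPATIENT, Provider.PRIMARY_CARE)
            )
        rate = cfg.specialist_visit_rate_pre if r < 0 else cfg.specialist_visit_rate_post
        n_spec = int(rng.poisson(rate))
        spec = _pick(rng, [Provider.ONCOLOGIST, Provider.PULMONOLOGIST])
        for d in _distinct_days(rng, lo, hi, n_spec):
            p.events.append(
                ClaimEvent(pid, d, EventKind.CONTACT, None, None,
                           Setting.OUTPATIENT, spec)
            )
        if treated and 0 <= r <= 2 and not no_post_events:
            n_h = int(rng.poisson(cfg.hospital_outpatient_rate))
            for d in _distinct_days(rng, lo, hi, n_h):
                p.events.append(
                    ClaimEvent(pid, d, EventKind.CONTACT, None, None,
                               Setting.OUTPATIENT, Provider.HOSPITAL)
                )
        n_rx = int(rng.poisson(cfg.chronic_rx_rate))
        for d in _distinct_days(rng, lo, hi, n_rx):
            p.events.append(
                ClaimEvent(pid, d, EventKind.DISPENSING, CodeSystem.ATC,
                           _pick(rng, _CHRONIC_ATC), Setting.NONE, Provider.PHARMACY)
            )


def _gen_background(pid: str, rng, cfg: ScenarioConfig) -> tuple[PatientRecord, TruthRecord]:
    """A non-LC insured person: chronic care noise, no C33/C34 coding."""
    p = PatientRecord(patient_id=pid)
    p.enrollment.append((cfg.data_start, cfg.data_end))
    young = rng.random() < 0.5
    lo, hi = cfg.age_young_range if young else cfg.age_old_range
    p.birth_year = 2015 - int(rng.integers(lo, hi + 1))
    p.gender = Gender.MALE if rng.random() < 0.5 else Gender.FEMALE
    p.municipality = Region.URBAN if rng.random() < cfg.urban_fraction else Region.RURAL
    q0 = Quarter.of(dt.date(2014, 1, 1))
    for r in range(16):
        q = q0.shift(r)
        n_gp = int(rng.poisson(cfg.gp_visit_rate))
        for d in _distinct_days(rng, q.start, q.end, n_gp):
            p.events.append(
                ClaimEvent(pid, d, EventKind.CONTACT, None, None,
                           Setting.OUTPATIENT, Provider.PRIMARY_CARE)
            )
        n_rx = int(rng.poisson(cfg.chronic_rx_rate))
        for d in _distinct_days(rng, q.start, q.end, n_rx):
            p.events.append(
                ClaimEvent(pid, d, EventKind.DISPENSING, CodeSystem.ATC,
                           _pick(rng, _CHRONIC_ATC), Setting.NONE, Provider.PHARMACY)
            )
        if rng.random() < 0.3:
            d = _rand_date(rng, q.start, q.end)
            p.events.append(
                ClaimEvent(pid, d, EventKind.DIAGNOSIS, CodeSystem.ICD10GM,
                           _pick(rng, _BENIGN_CODES), Setting.OUTPATIENT,
                           Provider.PRIMARY_CARE)
            )
    return p.sort(), TruthRecord(patient_id=pid, is_incident_lc=False)


def generate_population(
    cfg: ScenarioConfig, table: CodeTable | None = None
) -> tuple[list[PatientRecord], list[TruthRecord]]:
    """Generate a synthetic population with its ground-truth labels.

    Deterministic under ``cfg.seed``; each patient uses an independent
    stream derived from ``(seed, patient index)``.
    """
    table = table or load_default_table()
    pools = _therapy_pools(table)
    _validate_feasibility(cfg, pools)
    q_start = Quarter.of(cfg.index_period_start)
    q_end = Quarter.of(cfg.index_period_end)
    quarters = [Quarter.from_ordinal(o) for o in range(q_start.ordinal, q_end.ordinal + 1)]
    records, truths = [], []
    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        if rng.random() < cfg.lc_fraction:
            p, t = _gen_incident(pid, rng, cfg, pools, quarters)
        else:
            p, t = _gen_background(pid, rng, cfg)
        records.append(p)
        truths.append(t)
    return records, truths


# --------------------------------------------------------------------------
# edge-case panel


def edge_case_panel() -> tuple[list[PatientRecord], list[TruthRecord]]:
    """Hand-built boundary patients exercising every knife-edge rule."""
    full = (dt.date(2013, 1, 1), dt.date(2018, 12, 31))
    records: list[PatientRecord] = []
    truths: list[TruthRecord] = []

    def add(pid, events, stays=(), enrollment=full, birth_year=1950, truth=None):
        p = PatientRecord(
            patient_id=pid, birth_year=birth_year, gender=Gender.MALE,
            municipality=Region.URBAN, enrollment=[enrollment],
            events=list(events), stays=list(stays),
        )
        records.append(p.sort().flag_enrollment())
        truths.append(truth or TruthRecord(patient_id=pid, is_incident_lc=True))

    D = dt.date
    dx = lambda pid, d, code="C34", setting=Setting.INPATIENT, prov=Provider.HOSPITAL, conf=True: ClaimEvent(
        pid, d, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, code, setting, prov, conf
    )
    rx = lambda pid, d, code: ClaimEvent(
        pid, d, EventKind.DISPENSING, CodeSystem.ATC, code, Setting.NONE, Provider.PHARMACY
    )

    # diagnosis on a quarter's last day; therapy starts next quarter
    add(
        "EDGE-LASTDAY",
        [dx("EDGE-LASTDAY", D(2015, 3, 31)), rx("EDGE-LASTDAY", D(2015, 4, 5), "L01XC18")],
        stays=[HospitalStay("EDGE-LASTDAY", D(2015, 3, 31), D(2015, 4, 2))],
        truth=TruthRecord("EDGE-LASTDAY", True, "NSCLC", "no_mets", "2015Q1",
                          "Immunotherapy"),
    )

    # therapy event exactly 30 days after the line start stays in-window
    add(
        "EDGE-WINDOW30",
        [
            dx("EDGE-WINDOW30", D(2015, 4, 2)),
            rx("EDGE-WINDOW30", D(2015, 4, 10), "L01XA02"),
            rx("EDGE-WINDOW30", D(2015, 5, 10), "L01CD02"),  # start + 30 days
        ],
        stays=[HospitalStay("EDGE-WINDOW30", D(2015, 4, 2), D(2015, 4, 8))],
        truth=TruthRecord("EDGE-WINDOW30", True, "SCLC", "no_mets", "2015Q2",
                          "Chemotherapy"),
    )

    # simultaneous NSCLC- and SCLC-specific dispensings -> conflict
    add(
        "EDGE-CONFLICT",
        [
            dx("EDGE-CONFLICT", D(2015, 2, 10)),
            rx("EDGE-CONFLICT", D(2015, 2, 20), "L01XC18"),
            rx("EDGE-CONFLICT", D(2015, 3, 1), "L01XA02"),
        ],
        stays=[HospitalStay("EDGE-CONFLICT", D(2015, 2, 10), D(2015, 2, 15))],
        truth=TruthRecord("EDGE-CONFLICT", True, "NSCLC", "no_mets", "2015Q1",
                          "Immunotherapy"),
    )

    # C77 and C78 both coded -> distant metastases dominate
    add(
        "EDGE-C77C78",
        [
            dx("EDGE-C77C78", D(2015, 5, 4), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-C77C78", D(2015, 5, 4), code="C77", setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-C77C78", D(2015, 5, 4), code="C781", setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-C77C78", D(2015, 11, 2), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST),
        ],
        truth=TruthRecord("EDGE-C77C78", True, "none", "distant", "2015Q2"),
    )

    # single unconfirmed outpatient diagnosis -> never confirmed
    add(
        "EDGE-UNCONFIRMED",
        [dx("EDGE-UNCONFIRMED", D(2015, 7, 15), setting=Setting.OUTPATIENT,
            prov=Provider.PRIMARY_CARE, conf=False)],
        truth=TruthRecord("EDGE-UNCONFIRMED", True, "none", "", "2015Q3",
                          planned_exclusion_reason="not_confirmed"),
    )

    # hospital stay spanning a year boundary
    add(
        "EDGE-YEARSTAY",
        [dx("EDGE-YEARSTAY", D(2015, 11, 15))],
        stays=[
            HospitalStay("EDGE-YEARSTAY", D(2015, 11, 15), D(2015, 11, 18)),
            HospitalStay("EDGE-YEARSTAY", D(2015, 12, 28), D(2016, 1, 3)),
        ],
        truth=TruthRecord("EDGE-YEARSTAY", True, "none", "no_mets", "2015Q4"),
    )

    # washout boundary: prior coding at index-8 fails, index-9 passes
    add(
        "EDGE-WASHIN",
        [
            dx("EDGE-WASHIN", D(2013, 2, 1), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-WASHIN", D(2015, 2, 1)),
        ],
        stays=[HospitalStay("EDGE-WASHIN", D(2015, 2, 1), D(2015, 2, 6))],
        enrollment=(D(2012, 1, 1), D(2018, 12, 31)),
        truth=TruthRecord("EDGE-WASHIN", True, "none", "no_mets", "2015Q1",
                          planned_exclusion_reason="prior_lc_diagnosis"),
    )
    add(
        "EDGE-WASHOUT",
        [
            dx("EDGE-WASHOUT", D(2012, 12, 15), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-WASHOUT", D(2015, 2, 1)),
        ],
        stays=[HospitalStay("EDGE-WASHOUT", D(2015, 2, 1), D(2015, 2, 6))],
        enrollment=(D(2012, 1, 1), D(2018, 12, 31)),
        truth=TruthRecord("EDGE-WASHOUT", True, "none", "no_mets", "2015Q1"),
    )

    # M2Q confirmation inside vs outside the observation horizon
    add(
        "EDGE-M2QIN",
        [
            dx("EDGE-M2QIN", D(2016, 11, 10), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-M2QIN", D(2018, 11, 20), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
        ],
        enrollment=(D(2013, 1, 1), D(2019, 6, 30)),
        truth=TruthRecord("EDGE-M2QIN", True, "none", "no_mets", "2016Q4"),
    )
    add(
        "EDGE-M2QOUT",
        [
            dx("EDGE-M2QOUT", D(2016, 11, 10), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
            dx("EDGE-M2QOUT", D(2019, 1, 10), setting=Setting.OUTPATIENT,
               prov=Provider.PULMONOLOGIST, conf=False),
        ],
        enrollment=(D(2013, 1, 1), D(2019, 6, 30)),
        truth=TruthRecord("EDGE-M2QOUT", True, "none", "", "2016Q4",
                          planned_exclusion_reason="not_confirmed"),
    )

    # biomarker two-week rule: discharge at test-14 vs test-15 days
    for pid, admission, discharge in (
        ("EDGE-BIO14", D(2015, 3, 5), D(2015, 3, 10)),
        ("EDGE-BIO15", D(2015, 3, 4), D(2015, 3, 9)),
    ):
        add(
            pid,
            [
                dx(pid, admission),
                dx(pid, D(2015, 8, 3), setting=Setting.OUTPATIENT,
                   prov=Provider.PULMONOLOGIST, conf=False),
                dx(pid, D(2015, 11, 3), setting=Setting.OUTPATIENT,
                   prov=Provider.PULMONOLOGIST, conf=False),
                ClaimEvent(pid, D(2015, 3, 24), EventKind.PROCEDURE, CodeSystem.EBM,
                           "19321", Setting.OUTPATIENT, Provider.ONCOLOGIST),
            ],
            stays=[HospitalStay(pid, admission, discharge)],
            truth=TruthRecord(pid, True, "none", "no_mets", "2015Q1"),
        )

    return records, truths


def inject_edge_cases(
    records: list[PatientRecord], truths: list[TruthRecord] | None = None
):
    """Append the fixed edge-case panel to a generated population."""
    panel, panel_truths = edge_case_panel()
    records = list(records) + panel
    if truths is None:
        return records
    return records, list(truths) + panel_truths


# --------------------------------------------------------------------------
# truth table I/O

_TRUTH_COLUMNS = [
    "patient_id",
    "is_incident_lc",
    "true_type",
    "true_stage",
    "true_index_quarter",
    "true_first_line_group",
    "true_second_line_group",
    "planned_exclusion_reason",
    "true_other_category",
]


def write_truth(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_TRUTH_COLUMNS)
        for t in sorted(truths, key=lambda t: t.patient_id):
            w.writerow(
                [
                    t.patient_id,
                    int(t.is_incident_lc),
                    t.true_type,
                    t.true_stage,
                    t.true_index_quarter,
                    t.true_first_line_group,
                    t.true_second_line_group,
                    t.planned_exclusion_reason,
                    t.true_other_category,
                ]
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TruthRecord(
                    patient_id=row["patient_id"],
                    is_incident_lc=row["is_incident_lc"] in ("1", "true", "True"),
                    true_type=row["true_type"],
                    true_stage=row["true_stage"],
                    true_index_quarter=row["true_index_quarter"],
                    true_first_line_group=row["true_first_line_group"],
                    true_second_line_group=row["true_second_line_group"],
                    planned_exclusion_reason=row["planned_exclusion_reason"],
                    true_other_category=row["true_other_category"],
                )
            )
    return out
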