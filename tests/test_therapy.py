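"""Line construction, group hierarchy, cancer-type calls, other-categories."""

import datetime as dt

import pandas as pd
import pytest

from lungclaims.codes import CodeSystem, TreatmentGroup
from lungclaims.cohort import CohortConfig, select_cohort
from lungclaims.model import (
    ClaimEvent,
    EventKind,
    PatientRecord,
    Provider,
    Quarter,
    Setting,
)
from lungclaims.synth import ScenarioConfig, generate_population
from lungclaims.therapy import (
    OtherCategory,
    build_lines,
    categorize_untreated,
    classify_cancer_type,
    detect_first_line,
    detect_second_line,
)

from oracles import brute_force_lines

INDEX_Q = Quarter(2015, 2)


def _patient(events, pid="T"):
    p = PatientRecord(
        patient_id=pid,
        birth_year=1950,
        enrollment=[(dt.date(2013, 1, 1), dt.date(2018, 12, 31))],
    )
    p.events = [
        ClaimEvent(pid, d, kind, system, code, setting, provider)
        for (d, kind, system, code, setting, provider) in events
    ]
    return p.sort()


def _rx(day, code):
    return (day, EventKind.DISPENSING, CodeSystem.ATC, code, Setting.NONE, Provider.PHARMACY)


def _proc(day, system, code, setting=Setting.OUTPATIENT, provider=Provider.ONCOLOGIST):
    return (day, EventKind.PROCEDURE, system, code, setting, provider)


def _dx(day, code="C34"):
    return (day, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, code, Setting.OUTPATIENT,
            Provider.PULMONOLOGIST)


class TestFirstLine:
    def test_starts_at_earliest_therapy_event(self, table):
        p = _patient([_rx(dt.date(2015, 4, 10), "L01XC18"), _rx(dt.date(2015, 4, 20), "L01XC18")])
        ep = detect_first_line(p, INDEX_Q, table)
        assert ep.start_date == dt.date(2015, 4, 10)
        assert ep.window_end == dt.date(2015, 5, 10)
        assert ep.group is TreatmentGroup.IMMUNOTHERAPY

    def test_start_in_following_quarter_allowed(self, table):
        p = _patient([_rx(dt.date(2015, 8, 1), "L01XA02")])
        ep = detect_first_line(p, INDEX_Q, table)
        assert ep is not None and ep.start_date == dt.date(2015, 8, 1)

    def test_therapy_two_quarters_later_is_not_first_line(self, table):
        p = _patient([_rx(dt.date(2015, 10, 5), "L01XA02")])
        assert detect_first_line(p, INDEX_Q, table) is None

    def test_no_therapy_events(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1))])
        assert detect_first_line(p, INDEX_Q, table) is None


class TestGroupHierarchy:
    def test_immunotherapy_beats_chemotherapy(self, table):
        p = _patient([_rx(dt.date(2015, 5, 1), "L01XA02"), _rx(dt.date(2015, 5, 8), "L01XC18")])
        ep = detect_first_line(p, INDEX_Q, table)
        assert ep.group is TreatmentGroup.IMMUNOTHERAPY

    def test_radiotherapy_ebm_alone(self, table):
        p = _patient([_proc(dt.date(2015, 5, 1), CodeSystem.EBM, "25321",
                            provider=Provider.RADIOLOGIST)])
        ep = detect_first_line(p, INDEX_Q, table)
        assert ep.group is TreatmentGroup.RADIOTHERAPY

    def test_study_requires_same_quarter_companion(self, table):
        paired = _patient([
            _proc(dt.date(2015, 5, 4), CodeSystem.EBM, "13461"),
            _proc(dt.date(2015, 5, 4), CodeSystem.EBM, "02100"),
        ])
        ep = detect_first_line(paired, INDEX_Q, table)
        assert ep is not None and ep.group is TreatmentGroup.STUDY
        unpaired = _patient([_proc(dt.date(2015, 5, 4), CodeSystem.EBM, "13461")])
        assert detect_first_line(unpaired, INDEX_Q, table) is None

    def test_inpatient_radiotherapy_family_code(self, table):
        p = _patient([_proc(dt.date(2015, 5, 2), CodeSystem.OPS, "8-522",
                            setting=Setting.INPATIENT, provider=Provider.HOSPITAL)])
        ep = detect_first_line(p, INDEX_Q, table)
        assert ep.group is TreatmentGroup.RADIOTHERAPY


class TestSecondLine:
    def test_new_drug_after_window_opens_second_line(self, table):
        p = _patient([_rx(dt.date(2015, 4, 10), "L01XA02"), _rx(dt.date(2015, 6, 1), "L01XE03")])
        first = detect_first_line(p, INDEX_Q, table)
        second = detect_second_line(p, first, table)
        assert second.start_date == dt.date(2015, 6, 1)
        assert second.group is TreatmentGroup.INHIBITORS

    def test_repeats_of_first_line_drugs_do_not(self, table):
        p = _patient([_rx(dt.date(2015, 4, 10), "L01XA02"), _rx(dt.date(2015, 7, 1), "L01XA02")])
        first = detect_first_line(p, INDEX_Q, table)
        assert detect_second_line(p, first, table) is None

    def test_same_group_can_reopen(self, table):
        # new chemotherapy drug after a carboplatin-only first line
        p = _patient([_rx(dt.date(2015, 4, 10), "L01XA02"), _rx(dt.date(2015, 6, 15), "L01BC05")])
        first = detect_first_line(p, INDEX_Q, table)
        second = detect_second_line(p, first, table)
        assert second is not None and second.group is TreatmentGroup.CHEMOTHERAPY

    def test_event_on_window_boundary_stays_in_first_line(self, table):
        # day 30 belongs to the window; it must not open a second line
        p = _patient([_rx(dt.date(2015, 4, 10), "L01XA02"), _rx(dt.date(2015, 5, 10), "L01CD02")])
        first = detect_first_line(p, INDEX_Q, table)
        assert dt.date(2015, 5, 10) <= first.window_end
        assert detect_second_line(p, first, table) is None


class TestCancerTypeCall:
    def test_uniform_first_line_tags_decide(self, table):
        p = _patient([_rx(dt.date(2015, 5, 1), "L01XC18")])
        first = detect_first_line(p, INDEX_Q, table)
        call = classify_cancer_type(first, None, table)
        assert (call.call, call.basis) == ("NSCLC", "first_line")

    def test_untyped_first_line_defers_to_second(self, table):
        p = _patient([_rx(dt.date(2015, 5, 1), "L01XA01"), _rx(dt.date(2015, 7, 1), "L01XX17")])
        first = detect_first_line(p, INDEX_Q, table)
        second = detect_second_line(p, first, table)
        call = classify_cancer_type(first, second, table)
        assert (call.call, call.basis) == ("SCLC", "second_line")

    def test_mixed_tags_conflict(self, table):
        p = _patient([_rx(dt.date(2015, 5, 1), "L01XC18"), _rx(dt.date(2015, 5, 3), "L01XA02")])
        first = detect_first_line(p, INDEX_Q, table)
        call = classify_cancer_type(first, None, table)
        assert call.call == "unclassifiable" and call.conflicting

    def test_no_therapy_is_unclassifiable(self, table):
        call = classify_cancer_type(None, None, table, patient_id="T")
        assert (call.call, call.basis, call.conflicting) == ("unclassifiable", "none", False)

    def test_window_discipline_ignores_out_of_window_drugs(self, table):
        """A typed drug outside every line window cannot classify."""
        p = _patient([
            _proc(dt.date(2015, 5, 1), CodeSystem.EBM, "25321", provider=Provider.RADIOLOGIST),
            _proc(dt.date(2015, 5, 8), CodeSystem.EBM, "25321", provider=Provider.RADIOLOGIST),
        ])
        first = detect_first_line(p, INDEX_Q, table)
        assert first.group is TreatmentGroup.RADIOTHERAPY
        call = classify_cancer_type(first, None, table)
        assert call.call == "unclassifiable"


class TestOtherCategories:
    def test_inpatient_marker_is_other_treatment(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1)),
                      _proc(INDEX_Q.end + dt.timedelta(days=10), CodeSystem.OPS, "8-541",
                            setting=Setting.INPATIENT, provider=Provider.HOSPITAL)])
        assert categorize_untreated(p, INDEX_Q, table) is OtherCategory.OTHER_TREATMENT

    def test_silence_after_index_is_not_observable(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1))])
        assert categorize_untreated(p, INDEX_Q, table) is OtherCategory.NOT_OBSERVABLE_IN_LINE

    def test_late_therapy(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1)), _rx(dt.date(2015, 11, 2), "L01XA02")])
        assert categorize_untreated(p, INDEX_Q, table) is OtherCategory.LATE_THERAPY

    def test_no_followup_diagnosis(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1)),
                      (dt.date(2015, 9, 1), EventKind.CONTACT, None, None,
                       Setting.OUTPATIENT, Provider.PRIMARY_CARE)])
        assert categorize_untreated(p, INDEX_Q, table) is OtherCategory.NO_FOLLOWUP_DIAGNOSIS

    def test_surgery_then_bronchoscopy_then_none(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1)), _dx(dt.date(2015, 8, 1))])
        assert categorize_untreated(p, INDEX_Q, table, surgery_flag=True) is (
            OtherCategory.SURGERY_NO_THERAPY
        )
        assert categorize_untreated(
            p, INDEX_Q, table, surgery_flag=False, bronchoscopy_flag=True
        ) is OtherCategory.BRONCHOSCOPY_NO_SURGERY_NO_THERAPY
        assert categorize_untreated(p, INDEX_Q, table) is OtherCategory.NONE_OF_THE_ABOVE


def test_every_included_patient_gets_exactly_one_label(default_population, table):
    records, _ = default_population
    sel = select_cohort(records, CohortConfig(), table)
    by_id = {p.patient_id: p for p in records}
    lines, types, episodes = build_lines(by_id, sel, table)
    included = sel[sel["status"] == "included"]["patient_id"]
    assert set(types["patient_id"]) == set(included)
    for pid in included:
        first, _second = episodes[pid]
        if first is None:
            cat = categorize_untreated(by_id[pid], Quarter.parse(
                sel.set_index("patient_id").loc[pid, "index_quarter"]), table)
            assert isinstance(cat, OtherCategory)
        else:
            assert first.group is not TreatmentGroup.NONE


def test_line_detection_matches_brute_force_oracle(table):
    """Exact agreement with an independent day-by-day window simulator."""
    cfg = ScenarioConfig(n_patients=250, seed=17, lc_fraction=1.0,
                         treated_fraction=0.8, second_line_fraction=0.5,
                         exclusion_rates={"other_primary": 0.0,
                                          "short_pre_observation": 0.0,
                                          "short_post_observation": 0.0})
    records, truths = generate_population(cfg)
    truth_iq = {t.patient_id: t.true_index_quarter for t in truths}
    entries = list(table)
    mismatches = []
    for p in records:
        iq = Quarter.parse(truth_iq[p.patient_id])
        first = detect_first_line(p, iq, table)
        second = detect_second_line(p, first, table) if first else None
        bf_first, bf_second = brute_force_lines(p, iq.year, iq.q, entries)
        for got, want in ((first, bf_first), (second, bf_second)):
            if (got is None) != (want is None):
                mismatches.append(p.patient_id)
            elif got is not None and (
                got.start_date != want["start"]
                or got.window_end != want["window_end"]
                or got.group.value != want["group"]
            ):
                mismatches.append(p.patient_id)
    assert mismatches == []
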