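"""Therapist hierarchy and diagnostics detection with setting assignment."""

import datetime as dt
import random

from lungclaims.care import (
    CareConfig,
    attribute_therapist,
    detect_biomarker,
    detect_bronchoscopy,
    detect_surgery,
)
from lungclaims.codes import CodeSystem
from lungclaims.model import (
    ClaimEvent,
    EventKind,
    HospitalStay,
    PatientRecord,
    Provider,
    Quarter,
    Setting,
)
from lungclaims.therapy import LineEpisode

Q = Quarter(2015, 1)


def _patient(events, stays=()):
    p = PatientRecord(
        patient_id="T",
        enrollment=[(dt.date(2013, 1, 1), dt.date(2018, 12, 31))],
        events=list(events),
        stays=list(stays),
    )
    return p.sort()


def _dx(day, setting, provider, code="C34"):
    return ClaimEvent("T", day, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, code,
                      setting, provider)


def _proc(day, system, code):
    return ClaimEvent("T", day, EventKind.PROCEDURE, system, code,
                      Setting.OUTPATIENT, Provider.ONCOLOGIST)


class TestTherapist:
    def test_inpatient_hospital_beats_office_based(self, table):
        p = _patient([
            _dx(dt.date(2015, 2, 1), Setting.INPATIENT, Provider.HOSPITAL),
            _dx(dt.date(2015, 2, 5), Setting.OUTPATIENT, Provider.PULMONOLOGIST),
        ])
        call = attribute_therapist(p, Q, table)
        assert call.category == "hospital_inpatient"

    def test_outpatient_hospital_beats_specialists(self, table):
        p = _patient([
            _dx(dt.date(2015, 2, 1), Setting.OUTPATIENT, Provider.HOSPITAL),
            _dx(dt.date(2015, 2, 5), Setting.OUTPATIENT, Provider.ONCOLOGIST),
        ])
        assert attribute_therapist(p, Q, table).category == "hospital_outpatient"

    def test_specialty_order_within_office_based(self, table):
        p = _patient([
            _dx(dt.date(2015, 2, 1), Setting.OUTPATIENT, Provider.PRIMARY_CARE),
            _dx(dt.date(2015, 2, 5), Setting.OUTPATIENT, Provider.PULMONOLOGIST),
        ])
        call = attribute_therapist(p, Q, table)
        assert call.category == "other_physician"
        assert call.specialty is Provider.PULMONOLOGIST

    def test_single_primary_care_coder(self, table):
        p = _patient([_dx(dt.date(2015, 2, 1), Setting.OUTPATIENT, Provider.PRIMARY_CARE)])
        call = attribute_therapist(p, Q, table)
        assert (call.category, call.specialty) == ("other_physician", Provider.PRIMARY_CARE)

    def test_no_lc_coder_is_unknown(self, table):
        p = _patient([_dx(dt.date(2015, 2, 1), Setting.OUTPATIENT,
                          Provider.PRIMARY_CARE, code="J44")])
        assert attribute_therapist(p, Q, table).category == "unknown"

    def test_permutation_invariant(self, table):
        events = [
            _dx(dt.date(2015, 2, 1), Setting.OUTPATIENT, Provider.INTERNIST),
            _dx(dt.date(2015, 2, 10), Setting.INPATIENT, Provider.HOSPITAL),
            _dx(dt.date(2015, 3, 3), Setting.OUTPATIENT, Provider.RADIOLOGIST),
        ]
        rng = random.Random(0)
        results = set()
        for _ in range(6):
            rng.shuffle(events)
            p = PatientRecord(patient_id="T", events=list(events),
                              enrollment=[(dt.date(2013, 1, 1), dt.date(2018, 12, 31))])
            results.add(attribute_therapist(p, Q, table).category)
        assert results == {"hospital_inpatient"}


WINDOW = [(Q.start, Q.end)]


class TestBiomarker:
    def test_discharge_within_two_weeks_is_inpatient(self, table):
        test_day = dt.date(2015, 3, 24)
        p = _patient(
            [_proc(test_day, CodeSystem.EBM, "19321")],
            stays=[HospitalStay("T", dt.date(2015, 3, 5), test_day - dt.timedelta(days=14))],
        )
        flag = detect_biomarker(p, WINDOW, table)
        assert flag.setting is Setting.INPATIENT and flag.date == test_day

    def test_discharge_fifteen_days_before_is_outpatient(self, table):
        test_day = dt.date(2015, 3, 24)
        p = _patient(
            [_proc(test_day, CodeSystem.EBM, "19321")],
            stays=[HospitalStay("T", dt.date(2015, 3, 4), test_day - dt.timedelta(days=15))],
        )
        assert detect_biomarker(p, WINDOW, table).setting is Setting.OUTPATIENT

    def test_ops_family_child_code_detected(self, table):
        p = _patient([_proc(dt.date(2015, 2, 2), CodeSystem.OPS, "1-9910")])
        flag = detect_biomarker(p, WINDOW, table)
        assert flag.setting is Setting.OUTPATIENT

    def test_no_codes_no_flag(self, table):
        p = _patient([])
        flag = detect_biomarker(p, WINDOW, table)
        assert flag.setting is Setting.NONE and flag.date is None

    def test_setting_is_a_partition(self, table):
        # every detected test is exactly one of inpatient/outpatient
        p = _patient([_proc(dt.date(2015, 2, 2), CodeSystem.EBM, "19320")])
        flag = detect_biomarker(p, WINDOW, table)
        assert flag.setting in (Setting.INPATIENT, Setting.OUTPATIENT)


class TestBronchoscopy:
    def test_detected_in_index_quarter(self, table):
        p = _patient([_proc(dt.date(2015, 2, 20), CodeSystem.OPS, "1-620")])
        flag = detect_bronchoscopy(p, WINDOW, table)
        assert flag.detected

    def test_codes_before_window_ignored(self, table):
        p = _patient([_proc(dt.date(2014, 12, 20), CodeSystem.OPS, "1-620")])
        assert not detect_bronchoscopy(p, WINDOW, table).detected

    def test_second_line_context_window(self, table):
        # first line starts Apr 10, second line Jun 9: a bronchoscopy 45
        # days after the first-line start falls in the second-line window
        fl_start = dt.date(2015, 4, 10)
        sl_start = fl_start + dt.timedelta(days=60)
        windows = [(fl_start + dt.timedelta(days=31), sl_start + dt.timedelta(days=30))]
        p = _patient([_proc(fl_start + dt.timedelta(days=45), CodeSystem.EBM, "13662")])
        flag = detect_bronchoscopy(p, windows, table, line_context="second")
        assert flag.detected and flag.line_context == "second"


class TestSurgery:
    def _line(self, start):
        return LineEpisode("T", "first", start, start + dt.timedelta(days=30))

    def test_surgery_in_index_quarter_flagged(self, table):
        p = _patient([ClaimEvent("T", dt.date(2015, 2, 10), EventKind.PROCEDURE,
                                 CodeSystem.OPS, "5-324", Setting.INPATIENT,
                                 Provider.HOSPITAL)])
        assert detect_surgery(p, Q, None, table).detected

    def test_surgery_outside_relevant_quarters_not_flagged(self, table):
        p = _patient([ClaimEvent("T", dt.date(2015, 11, 10), EventKind.PROCEDURE,
                                 CodeSystem.OPS, "5-324", Setting.INPATIENT,
                                 Provider.HOSPITAL)])
        assert not detect_surgery(p, Q, self._line(dt.date(2015, 4, 2)), table).detected

    def test_first_line_start_quarter_counts(self, table):
        p = _patient([ClaimEvent("T", dt.date(2015, 4, 20), EventKind.PROCEDURE,
                                 CodeSystem.OPS, "5-335", Setting.INPATIENT,
                                 Provider.HOSPITAL)])
        assert detect_surgery(p, Q, self._line(dt.date(2015, 4, 2)), table).detected

    def test_empty_surgery_code_set_never_flags(self):
        from lungclaims.codes import load_default_table

        bare = load_default_table(include_surgery=False)
        p = _patient([ClaimEvent("T", dt.date(2015, 2, 10), EventKind.PROCEDURE,
                                 CodeSystem.OPS, "5-324", Setting.INPATIENT,
                                 Provider.HOSPITAL)])
        assert not detect_surgery(p, Q, None, bare).detected
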