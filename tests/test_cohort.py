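"""Index quarter, confirmation, washout, exclusion cascade, staging."""

import datetime as dt

import pandas as pd
import pytest

from lungclaims.codes import CodeSystem
from lungclaims.cohort import (
    CohortConfig,
    ExclusionReason,
    Stage,
    apply_exclusions,
    assign_stage,
    confirm_diagnosis,
    find_index_quarter,
    is_newly_diagnosed,
    is_other_primary_code,
    select_cohort,
    stratify_demographics,
)
from lungclaims.model import (
    ClaimEvent,
    EventKind,
    PatientRecord,
    Provider,
    Quarter,
    Setting,
)

from oracles import brute_force_stage

CFG = CohortConfig()


def _patient(events, enrollment=(dt.date(2013, 1, 1), dt.date(2018, 12, 31)), birth_year=1950):
    p = PatientRecord(patient_id="T", birth_year=birth_year, enrollment=[enrollment])
    p.events = list(events)
    return p.sort()


def _dx(date, code="C34", setting=Setting.OUTPATIENT, confirmed=False,
        provider=Provider.PULMONOLOGIST):
    return ClaimEvent("T", date, EventKind.DIAGNOSIS, CodeSystem.ICD10GM, code,
                      setting, provider, confirmed)


class TestIndexQuarter:
    def test_earliest_quarter_in_period_wins(self, table):
        p = _patient([_dx(dt.date(2015, 8, 1)), _dx(dt.date(2016, 2, 1))])
        assert find_index_quarter(p, CFG, table) == Quarter(2015, 3)

    def test_no_lc_diagnosis_gives_none(self, table):
        p = _patient([_dx(dt.date(2015, 8, 1), code="C50")])
        assert find_index_quarter(p, CFG, table) is None

    def test_diagnosis_outside_period_ignored(self, table):
        p = _patient([_dx(dt.date(2014, 11, 1))])
        assert find_index_quarter(p, CFG, table) is None


class TestWashout:
    def test_no_prior_coding_is_new(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1))])
        assert is_newly_diagnosed(p, Quarter(2015, 2), table)

    def test_prior_coding_inside_washout_fails(self, table):
        # index 2015Q2; 2013Q3 = index-7
        p = _patient([_dx(dt.date(2013, 8, 1)), _dx(dt.date(2015, 5, 1))])
        assert not is_newly_diagnosed(p, Quarter(2015, 2), table)

    def test_prior_coding_before_washout_passes(self, table):
        # 2013Q1 = index-9 for index 2015Q2
        p = _patient([_dx(dt.date(2013, 2, 1)), _dx(dt.date(2015, 5, 1))])
        assert is_newly_diagnosed(p, Quarter(2015, 2), table)

    def test_boundary_shift_flips_outcome(self, table):
        """Moving the prior coding from index-8 to index-9 flips the check."""
        index_q = Quarter(2015, 1)
        inside = _patient([_dx(index_q.shift(-8).start), _dx(dt.date(2015, 2, 1))],
                          enrollment=(dt.date(2012, 1, 1), dt.date(2018, 12, 31)))
        outside = _patient([_dx(index_q.shift(-9).end), _dx(dt.date(2015, 2, 1))],
                           enrollment=(dt.date(2012, 1, 1), dt.date(2018, 12, 31)))
        assert not is_newly_diagnosed(inside, index_q, table)
        assert is_newly_diagnosed(outside, index_q, table)


class TestConfirmation:
    def test_two_outpatient_quarters_confirm(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1)), _dx(dt.date(2015, 11, 1))])
        assert confirm_diagnosis(p, Quarter(2015, 2), CFG, table)

    def test_single_outpatient_quarter_insufficient(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1))])
        assert not confirm_diagnosis(p, Quarter(2015, 2), CFG, table)

    def test_one_confirmed_inpatient_coding_confirms(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1), setting=Setting.INPATIENT,
                          confirmed=True, provider=Provider.HOSPITAL)])
        assert confirm_diagnosis(p, Quarter(2015, 2), CFG, table)

    def test_unconfirmed_inpatient_coding_does_not(self, table):
        p = _patient([_dx(dt.date(2015, 5, 1), setting=Setting.INPATIENT,
                          confirmed=False, provider=Provider.HOSPITAL)])
        assert not confirm_diagnosis(p, Quarter(2015, 2), CFG, table)

    def test_second_quarter_beyond_horizon_does_not_count(self, table):
        p = _patient([_dx(dt.date(2016, 11, 1)), _dx(dt.date(2019, 2, 1))],
                     enrollment=(dt.date(2013, 1, 1), dt.date(2019, 6, 30)))
        assert not confirm_diagnosis(p, Quarter(2016, 4), CFG, table)
        # moving it inside the horizon flips the outcome
        p2 = _patient([_dx(dt.date(2016, 11, 1)), _dx(dt.date(2018, 11, 1))],
                      enrollment=(dt.date(2013, 1, 1), dt.date(2019, 6, 30)))
        assert confirm_diagnosis(p2, Quarter(2016, 4), CFG, table)


class TestExclusionCascade:
    def _confirmed_base(self):
        return [
            _dx(dt.date(2015, 5, 2), setting=Setting.INPATIENT, confirmed=True,
                provider=Provider.HOSPITAL),
            _dx(dt.date(2015, 8, 2)),
            _dx(dt.date(2015, 11, 2)),
        ]

    def test_other_primary_tumor_excludes(self, table):
        p = _patient(self._confirmed_base() + [_dx(dt.date(2016, 2, 1), code="C50")])
        res = apply_exclusions(p, Quarter(2015, 2), CFG, table)
        assert res.status == "excluded"
        assert res.exclusion_reason is ExclusionReason.OTHER_PRIMARY_TUMOR

    def test_c61_exempt_from_other_primary_rule(self, table):
        p = _patient(self._confirmed_base() + [_dx(dt.date(2016, 2, 1), code="C61")])
        res = apply_exclusions(p, Quarter(2015, 2), CFG, table)
        assert res.status == "included"

    def test_short_pre_observation_excludes(self, table):
        # enrollment starts 5 quarters before the index quarter
        p = _patient(self._confirmed_base(),
                     enrollment=(Quarter(2015, 2).shift(-5).start, dt.date(2018, 12, 31)))
        res = apply_exclusions(p, Quarter(2015, 2), CFG, table)
        assert res.exclusion_reason is ExclusionReason.INSUFFICIENT_PRE_OBSERVATION

    def test_short_post_observation_excludes(self, table):
        p = _patient(
            [
                _dx(dt.date(2015, 5, 2), setting=Setting.INPATIENT, confirmed=True,
                    provider=Provider.HOSPITAL)
            ],
            enrollment=(dt.date(2013, 1, 1), Quarter(2015, 2).end),
        )
        res = apply_exclusions(p, Quarter(2015, 2), CFG, table)
        assert res.exclusion_reason is ExclusionReason.INSUFFICIENT_POST_OBSERVATION

    def test_first_failing_check_wins(self, table):
        # unconfirmed AND other primary: confirmation is checked first
        p = _patient([_dx(dt.date(2015, 5, 2)), _dx(dt.date(2015, 6, 2), code="C50")])
        res = apply_exclusions(p, Quarter(2015, 2), CFG, table)
        assert res.exclusion_reason is ExclusionReason.NOT_CONFIRMED


@pytest.mark.parametrize(
    "code,expected",
    [
        ("C50", True),
        ("C001", True),
        ("C75", True),
        ("C76", False),  # beyond C75
        ("C33", False),
        ("C341", False),
        ("C44", False),
        ("C61", False),
        ("C7", False),  # truncated
        ("D50", False),
    ],
)
def test_other_primary_code_range(code, expected):
    assert is_other_primary_code(code) is expected


class TestStage:
    def test_examples(self, table):
        base = [_dx(dt.date(2015, 5, 2))]
        assert assign_stage(_patient(base), Quarter(2015, 2), table) is Stage.NO_METS
        with_c77 = base + [_dx(dt.date(2015, 5, 2), code="C77")]
        assert assign_stage(_patient(with_c77), Quarter(2015, 2), table) is Stage.LYMPH_NODE_METS
        with_both = with_c77 + [_dx(dt.date(2015, 5, 2), code="C781")]
        assert assign_stage(_patient(with_both), Quarter(2015, 2), table) is Stage.DISTANT_METS

    def test_codes_outside_index_quarter_ignored(self, table):
        p = _patient([_dx(dt.date(2015, 5, 2)), _dx(dt.date(2015, 8, 2), code="C78")])
        assert assign_stage(p, Quarter(2015, 2), table) is Stage.NO_METS

    @pytest.mark.parametrize(
        "codes",
        [
            {"C34"},
            {"C34", "C77"},
            {"C34", "C78"},
            {"C34", "C77", "C781"},
            {"C34", "C793"},
            {"C34", "C770"},
        ],
    )
    def test_matches_rule_cascade_oracle(self, table, codes):
        events = [_dx(dt.date(2015, 5, 2), code=c) for c in sorted(codes)]
        got = assign_stage(_patient(events), Quarter(2015, 2), table)
        assert got.value == brute_force_stage(codes)


class TestDemographics:
    def test_age_boundary_at_60(self):
        p = _patient([], birth_year=1955)
        assert stratify_demographics(p, Quarter(2015, 2))[0] == "<=60"
        p = _patient([], birth_year=1954)
        assert stratify_demographics(p, Quarter(2015, 2))[0] == ">60"

    def test_missing_birth_year_reported_unknown(self):
        p = _patient([], birth_year=None)
        assert stratify_demographics(p, Quarter(2015, 2))[0] == "unknown"


def test_partition_of_candidates(default_population, table):
    """included + per-reason exclusions must equal the candidate count."""
    records, _ = default_population
    sel = select_cohort(records, CFG, table)
    total = len(sel)
    included = (sel["status"] == "included").sum()
    excluded = (sel["status"] == "excluded").sum()
    assert included + excluded == total
    reason_sum = sel[sel["status"] == "excluded"]["exclusion_reason"].value_counts().sum()
    assert reason_sum == excluded
    assert (sel.loc[sel["status"] == "included", "exclusion_reason"] == "none").all()


def test_planned_exclusions_recovered_exactly(default_population, table):
    """On non-overlapping planned exclusions, pipeline reasons match truth."""
    records, truths = default_population
    sel = select_cohort(records, CFG, table)
    truth = pd.DataFrame([t.__dict__ for t in truths])
    merged = sel.merge(truth, on="patient_id")
    planned = merged[merged["planned_exclusion_reason"] != "none"]
    assert len(planned) > 0
    mapping = {
        "other_primary": "other_primary_tumor",
        "short_pre_observation": "insufficient_pre_observation",
        "short_post_observation": "insufficient_post_observation",
    }
    assert (
        planned["exclusion_reason"]
        == planned["planned_exclusion_reason"].map(mapping)
    ).all()
    unplanned = merged[merged["planned_exclusion_reason"] == "none"]
    assert (unplanned["status"] == "included").all()
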