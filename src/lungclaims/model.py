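"""Longitudinal claims data model: quarters, events, stays, patients.

The calendar quarter is the fundamental time unit of German SHI claims
analysis -- outpatient diagnoses are billed per quarter, and all cohort
rules (index quarter, washout, M2Q confirmation, observation windows)
are quarter arithmetic.  :class:`Quarter` provides that arithmetic;
:class:`ClaimEvent`, :class:`HospitalStay`, and :class:`PatientRecord`
carry the event stream the rest of the pipeline consumes.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import total_ordering
from typing import Iterable, Sequence

from .codes import CodeSystem

__all__ = [
    "Quarter",
    "quarter_of",
    "quarter_shift",
    "EventKind",
    "Setting",
    "Provider",
    "StayMode",
    "Gender",
    "Region",
    "ClaimEvent",
    "HospitalStay",
    "PatientRecord",
    "SPECIALIST_PROVIDERS",
]


@total_ordering
@dataclass(frozen=True)
class Quarter:
    """A calendar quarter, e.g. ``Quarter(2015, 1)`` = Jan-Mar 2015."""

    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValueError(f"quarter index must be 1-4, got {self.q}")

    # ordinal arithmetic -------------------------------------------------

    @property
    def ordinal(self) -> int:
        return self.year * 4 + (self.q - 1)

    @classmethod
    def from_ordinal(cls, n: int) -> "Quarter":
        return cls(n // 4, n % 4 + 1)

    def shift(self, n: int) -> "Quarter":
        return Quarter.from_ordinal(self.ordinal + n)

    def __add__(self, n: int) -> "Quarter":
        return self.shift(n)

    def __sub__(self, other: "Quarter") -> int:
        return self.ordinal - other.ordinal

    def __lt__(self, other: "Quarter") -> bool:
        return self.ordinal < other.ordinal

    # calendar view ------------------------------------------------------

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 3 * self.q - 2, 1)

    @property
    def end(self) -> dt.date:
        return (self + 1).start - dt.timedelta(days=1)

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def __contains__(self, d: dt.date) -> bool:
        return self.start <= d <= self.end

    @classmethod
    def of(cls, d: dt.date) -> "Quarter":
        return cls(d.year, (d.month - 1) // 3 + 1)

    # formatting ---------------------------------------------------------

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"

    @classmethod
    def parse(cls, s: str) -> "Quarter":
        m = re.fullmatch(r"(\d{4})Q([1-4])", s.strip())
        if not m:
            raise ValueError(f"cannot parse quarter {s!r}")
        return cls(int(m.group(1)), int(m.group(2)))


def quarter_of(d: dt.date) -> Quarter:
    """Calendar quarter containing *d*."""
    return Quarter.of(d)


def quarter_shift(q: Quarter, n: int) -> Quarter:
    """*q* shifted by *n* quarters (negative = earlier)."""
    return q.shift(n)


class EventKind(str, Enum):
    DIAGNOSIS = "diagnosis"
    DISPENSING = "dispensing"
    PROCEDURE = "procedure"
    STAY_DAY = "stay_day"
    CONTACT = "contact"


class Setting(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    NONE = "none"


class Provider(str, Enum):
    HOSPITAL = "hospital"
    ONCOLOGIST = "oncologist"
    PULMONOLOGIST = "pulmonologist"
    RADIOLOGIST = "radiologist"
    INTERNIST = "internist"
    PRIMARY_CARE = "primary_care"
    OTHER_OFFICE_BASED = "other_office_based"
    PHARMACY = "pharmacy"
    UNKNOWN = "unknown"


#: Office-based providers counted as "specialist" in the time-expenditure
#: analysis (everything office-based that is not primary care).
SPECIALIST_PROVIDERS = frozenset(
    {
        Provider.ONCOLOGIST,
        Provider.PULMONOLOGIST,
        Provider.RADIOLOGIST,
        Provider.INTERNIST,
        Provider.OTHER_OFFICE_BASED,
    }
)


class StayMode(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT_HOSPITAL = "outpatient_hospital"


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Region(str, Enum):
    URBAN = "urban"
    RURAL = "rural"


@dataclass(frozen=True)
class ClaimEvent:
    """One billed fact: a diagnosis, dispensing, procedure, or contact.

    ``confirmed`` carries the German diagnosis-certainty marker and is
    only meaningful for diagnoses.  ``in_enrollment`` is derived at load
    time (events dated outside every enrollment interval are kept but
    flagged); it is not part of the serialized row.
    """

    patient_id: str
    date: dt.date
    kind: EventKind
    system: CodeSystem | None = None
    code: str | None = None
    setting: Setting = Setting.NONE
    provider: Provider = Provider.UNKNOWN
    confirmed: bool = False
    in_enrollment: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.kind is EventKind.DISPENSING and self.system is not CodeSystem.ATC:
            raise ValueError(f"dispensing event must carry an ATC code ({self})")
        if self.kind is EventKind.DIAGNOSIS and self.system is not CodeSystem.ICD10GM:
            raise ValueError(f"diagnosis event must carry an ICD-10-GM code ({self})")

    @property
    def quarter(self) -> Quarter:
        return Quarter.of(self.date)


@dataclass(frozen=True)
class HospitalStay:
    """A hospital stay interval; days are counted on a closed interval."""

    patient_id: str
    admission: dt.date
    discharge: dt.date
    mode: StayMode = StayMode.INPATIENT

    def __post_init__(self) -> None:
        if self.admission > self.discharge:
            raise ValueError(
                f"stay admission {self.admission} after discharge {self.discharge}"
            )

    @property
    def n_days(self) -> int:
        return (self.discharge - self.admission).days + 1

    def days_in_quarter(self, q: Quarter) -> int:
        """Calendar days of this stay falling inside quarter *q*.

        A stay spanning a quarter boundary contributes its days to each
        quarter by calendar membership, so the per-quarter counts always
        sum to the stay length.
        """
        lo = max(self.admission, q.start)
        hi = min(self.discharge, q.end)
        return max(0, (hi - lo).days + 1)

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        return self.admission <= end and self.discharge >= start


def _merge_intervals(
    intervals: Iterable[tuple[dt.date, dt.date]]
) -> list[tuple[dt.date, dt.date]]:
    """Merge intervals, joining neighbours with gaps < 1 day."""
    out: list[tuple[dt.date, dt.date]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + dt.timedelta(days=1):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


_EVENT_SORT_KEY = lambda ev: (  # noqa: E731 - used in two places
    ev.date,
    ev.kind.value,
    ev.system.value if ev.system else "",
    ev.code or "",
    ev.setting.value,
    ev.provider.value,
)


@dataclass
class PatientRecord:
    """Demographics, enrollment, and the event stream of one insured person."""

    patient_id: str
    birth_year: int | None = None
    gender: Gender = Gender.FEMALE
    municipality: Region = Region.URBAN
    enrollment: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    events: list[ClaimEvent] = field(default_factory=list)
    stays: list[HospitalStay] = field(default_factory=list)

    def sort(self) -> "PatientRecord":
        self.events.sort(key=_EVENT_SORT_KEY)
        self.stays.sort(key=lambda s: (s.admission, s.discharge, s.mode.value))
        self.enrollment = _merge_intervals(self.enrollment)
        return self

    def enrolled_on(self, d: dt.date) -> bool:
        return any(s <= d <= e for s, e in self.enrollment)

    def enrollment_covers(self, start: dt.date, end: dt.date) -> bool:
        """Continuous enrollment over [start, end] (gaps < 1 day tolerated)."""
        for s, e in _merge_intervals(self.enrollment):
            if s <= start and end <= e:
                return True
        return False

    @property
    def enrollment_start(self) -> dt.date | None:
        return min((s for s, _ in self.enrollment), default=None)

    @property
    def enrollment_end(self) -> dt.date | None:
        return max((e for _, e in self.enrollment), default=None)

    def flag_enrollment(self) -> "PatientRecord":
        """Re-derive the ``in_enrollment`` flag on every event."""
        self.events = [
            ev
            if self.enrolled_on(ev.date) == ev.in_enrollment
            else replace(ev, in_enrollment=self.enrolled_on(ev.date))
            for ev in self.events
        ]
        return self

    def events_in_quarter(self, q: Quarter) -> list[ClaimEvent]:
        return [ev for ev in self.events if ev.date in q]
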