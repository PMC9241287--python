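"""Code registry for ICD-10-GM, ATC, OPS, and EBM code sets.

German claims data identify everything by billing codes: diagnoses
(ICD-10-GM), dispensed drugs (ATC), inpatient procedures (OPS), and
outpatient services (EBM).  This module holds the machine-readable
registry of every code set the pipeline relies on -- the drug/procedure
table that maps codes to treatment groups and cancer types, the lung
cancer and metastasis diagnosis codes, and the diagnostic-procedure code
sets -- together with the normalization and prefix-matching semantics
those codes need.

Source catalogues print codes inconsistently ("8–542", "1-991 ×",
"C34.1"); :func:`normalize_code` maps all of these onto a canonical form
(uppercase, no dots, ASCII hyphens) so that lookups are exact-string
operations.  A trailing "×"/"x" wildcard marks a code *family*; family
entries, and every 3-character ICD-10 code, match all of their children
by prefix.

Codes are treated as opaque strings: no validation against the official
catalogues is attempted.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CodeSystem",
    "TreatmentGroup",
    "CancerType",
    "Role",
    "CodeEntry",
    "CodeTable",
    "InvalidCodeError",
    "normalize_code",
    "parse_code",
    "code_matches",
    "load_default_table",
    "load_surgery_table",
]


class CodeSystem(str, Enum):
    """Coding system of a billed fact."""

    ICD10GM = "ICD10GM"
    ATC = "ATC"
    OPS = "OPS"
    EBM = "EBM"


class TreatmentGroup(str, Enum):
    """Treatment groups in hierarchy order (highest priority first)."""

    IMMUNOTHERAPY = "Immunotherapy"
    INHIBITORS = "Inhibitors"
    CHEMOTHERAPY = "Chemotherapy"
    RADIOTHERAPY = "Radiotherapy"
    STUDY = "Study"
    NONE = "none"


#: Hierarchy used when several treatment groups are billed in one
#: episode window: the highest-priority group present wins.
GROUP_PRIORITY: tuple[TreatmentGroup, ...] = (
    TreatmentGroup.IMMUNOTHERAPY,
    TreatmentGroup.INHIBITORS,
    TreatmentGroup.CHEMOTHERAPY,
    TreatmentGroup.RADIOTHERAPY,
    TreatmentGroup.STUDY,
)


class CancerType(str, Enum):
    NSCLC = "NSCLC"
    SCLC = "SCLC"
    NONE = "none"


class Role(str, Enum):
    """What a code entry is used for in the pipeline."""

    LC_DIAGNOSIS = "lc_diagnosis"
    OTHER_PRIMARY = "other_primary"
    LYMPH_MET = "lymph_met"
    DISTANT_MET = "distant_met"
    THERAPY = "therapy"
    BIOMARKER = "biomarker"
    BRONCHOSCOPY = "bronchoscopy"
    SURGERY = "surgery"
    STUDY_MARKER = "study_marker"
    INPATIENT_CHEMO_MARKER = "inpatient_chemo_marker"
    OTHER = "other"


class InvalidCodeError(ValueError):
    """Raised when a raw code string cannot be normalized."""


# canonical form: uppercase alphanumerics separated by single hyphens
_CANONICAL_RE = re.compile(r"^[A-Z0-9]+(?:-[A-Z0-9]+)*$")
# trailing wildcard: "×" / "*" anywhere at the end, x/X after
# whitespace, or a lowercase x directly after a digit (never after a
# letter or dot, so OPS suffix letters like "6-001.a" survive; never an
# uppercase X after a digit, so canonical output is a fixed point)
_WILDCARD_RE = re.compile(r"(?:\s+[x×X*]|(?<=\d)[x×*]|[×*])\s*$")


def parse_code(system: CodeSystem, raw: str) -> tuple[str, bool]:
    """Normalize *raw* and report whether it carried a wildcard marker.

    Returns ``(canonical, is_prefix)``.  Normalization uppercases,
    strips dots and internal whitespace, converts en/em dashes to ASCII
    hyphens, and removes a trailing wildcard marker ("×", "*", or a
    standalone "x").  Idempotent on its own output.
    """
    s = raw.strip()
    if not s:
        raise InvalidCodeError("empty code string")
    s = s.replace("–", "-").replace("—", "-").replace("−", "-")
    is_prefix = False
    m = _WILDCARD_RE.search(s)
    if m:
        is_prefix = True
        s = s[: m.start()].rstrip()
    s = s.replace(".", "").replace(" ", "").upper()
    s = re.sub(r"-+", "-", s).strip("-")
    if not s:
        raise InvalidCodeError(f"code {raw!r} is empty after normalization")
    if not _CANONICAL_RE.match(s):
        raise InvalidCodeError(f"code {raw!r} normalizes to invalid {s!r}")
    return s, is_prefix


def normalize_code(system: CodeSystem, raw: str) -> str:
    """Canonical form of *raw* (see :func:`parse_code`)."""
    return parse_code(system, raw)[0]


@dataclass(frozen=True)
class CodeEntry:
    """One row of the code registry."""

    system: CodeSystem
    code: str
    is_prefix: bool = False
    label: str = ""
    treatment_group: TreatmentGroup = TreatmentGroup.NONE
    cancer_type: CancerType = CancerType.NONE
    role: Role = Role.OTHER

    def __post_init__(self) -> None:
        if not _CANONICAL_RE.match(self.code):
            raise InvalidCodeError(f"non-canonical code {self.code!r}")
        if self.cancer_type is not CancerType.NONE and self.role is not Role.THERAPY:
            raise ValueError(
                f"{self.system.value} {self.code}: cancer_type set on non-therapy entry"
            )

    def matches(self, system: CodeSystem, observed: str) -> bool:
        return code_matches(self, system, observed)


def code_matches(entry: CodeEntry, system: CodeSystem, observed: str) -> bool:
    """Does a canonical *observed* code fall under *entry*?

    True iff the systems agree and either the codes are equal or the
    entry denotes a family (explicit wildcard, or a 3-character ICD-10
    code, which by catalogue structure covers all its 4/5-character
    children) and *observed* extends it.
    """
    if entry.system is not system:
        return False
    if observed == entry.code:
        return True
    prefixy = entry.is_prefix or (
        entry.system is CodeSystem.ICD10GM and len(entry.code) == 3
    )
    return prefixy and observed.startswith(entry.code)


class CodeTable:
    """A set of :class:`CodeEntry` rows with lookup helpers.

    Entries are unique on ``(system, code)``.  Exact lookups use a dict;
    prefix entries are scanned per system (the sets involved are tiny).
    """

    def __init__(self, entries: Iterable[CodeEntry], version: str = "unversioned"):
        self.version = version
        self._exact: dict[tuple[CodeSystem, str], CodeEntry] = {}
        self._prefix: dict[CodeSystem, list[CodeEntry]] = {s: [] for s in CodeSystem}
        self.entries: list[CodeEntry] = []
        for e in entries:
            key = (e.system, e.code)
            if key in self._exact:
                raise ValueError(f"duplicate code entry {e.system.value} {e.code}")
            self._exact[key] = e
            self.entries.append(e)
            if e.is_prefix or (e.system is CodeSystem.ICD10GM and len(e.code) == 3):
                self._prefix[e.system].append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodeEntry]:
        return iter(self.entries)

    def get(self, system: CodeSystem, code: str) -> CodeEntry | None:
        return self._exact.get((system, code))

    def match(self, system: CodeSystem, observed: str) -> list[CodeEntry]:
        """All entries that *observed* falls under (exact match first)."""
        out: list[CodeEntry] = []
        exact = self._exact.get((system, observed))
        if exact is not None:
            out.append(exact)
        for e in self._prefix[system]:
            if e is exact:
                continue
            if code_matches(e, system, observed):
                out.append(e)
        return out

    def roles(self, system: CodeSystem, observed: str) -> set[Role]:
        return {e.role for e in self.match(system, observed)}

    def has_role(self, system: CodeSystem, observed: str, role: Role) -> bool:
        return any(e.role is role for e in self.match(system, observed))

    def lookup_therapy(
        self, code: str, system: CodeSystem
    ) -> tuple[TreatmentGroup, CancerType]:
        """Treatment-group / cancer-type assignment of a therapy code.

        ``(none, none)`` when the code is not a therapy code.
        """
        for e in self.match(system, code):
            if e.role is Role.THERAPY:
                return e.treatment_group, e.cancer_type
        return TreatmentGroup.NONE, CancerType.NONE

    def with_role(self, role: Role) -> list[CodeEntry]:
        return [e for e in self.entries if e.role is role]

    def merge(self, other: "CodeTable") -> "CodeTable":
        return CodeTable(
            list(self.entries) + list(other.entries),
            version=f"{self.version}+{other.version}",
        )

    # ---------------------------------------------------------- I/O

    @classmethod
    def from_csv(cls, path: str | Path, version: str | None = None) -> "CodeTable":
        path = Path(path)
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                system = CodeSystem(row["system"])
                code, wild = parse_code(system, row["code"])
                entries.append(
                    CodeEntry(
                        system=system,
                        code=code,
                        is_prefix=wild or row["is_prefix"].strip() in ("1", "true", "True"),
                        label=row.get("label", ""),
                        treatment_group=TreatmentGroup(row.get("treatment_group", "none")),
                        cancer_type=CancerType(row.get("cancer_type", "none")),
                        role=Role(row.get("role", "other")),
                    )
                )
        return cls(entries, version=version or path.stem)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(
                ["system", "code", "is_prefix", "label", "treatment_group", "cancer_type", "role"]
            )
            for e in self.entries:
                w.writerow(
                    [
                        e.system.value,
                        e.code,
                        int(e.is_prefix),
                        e.label,
                        e.treatment_group.value,
                        e.cancer_type.value,
                        e.role.value,
                    ]
                )


def _resource_path(name: str) -> Path:
    return Path(str(resources.files("lungclaims.resources") / name))


def load_default_table(include_surgery: bool = True) -> CodeTable:
    """The bundled drug/procedure/diagnosis registry.

    With ``include_surgery`` the synthetic placeholder surgery code set
    is merged in (the authoritative surgery OPS list is distributed as a
    configurable resource precisely because it varies between users).
    """
    table = CodeTable.from_csv(_resource_path("code_table_v1.csv"), version="table1-v1")
    if include_surgery:
        table = table.merge(load_surgery_table())
    return table


def load_surgery_table() -> CodeTable:
    """Placeholder surgery OPS families (synthetic, user-replaceable)."""
    return CodeTable.from_csv(
        _resource_path("surgery_codes_synthetic.csv"), version="surgery-synthetic"
    )
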