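"""Core data model for health-insurance claims.

A claim is one billing record: a date span, an ordered list of ICD-10
diagnosis codes (position 1 = primary/main diagnosis), a set of procedure
evidence flags, and the identity and tier of the billing hospital.  Claims
are grouped per patient; death is recorded as a patient-level date because
"in-episode death" is only meaningful relative to a hospitalization episode.
"""

from __future__ import annotations

import datetime
import enum
import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence

__all__ = [
    "Disease",
    "EvidenceFlag",
    "HospitalType",
    "DiagnosisEntry",
    "Claim",
    "PatientRecord",
    "CodeScope",
    "AMI_CODES",
    "STROKE_CODES",
    "DISEASE_CODES",
    "matches_code_group",
    "claim_sort_key",
]

_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]*(\.[0-9A-Z]+)?$")


class Disease(str, enum.Enum):
    """Disease streams handled by the identification algorithms."""

    AMI = "AMI"
    STROKE = "STROKE"


class EvidenceFlag(str, enum.Enum):
    """Closed enumeration of procedure/service evidence used by the rules.

    ``STROKE_INTERVENTION`` collapses intravenous thrombolysis, endovascular
    treatment, coil embolization and other stroke-specific therapeutic
    interventions into a single flag; ``BRAIN_IMAGING`` covers CT, MRI and
    cerebral angiography alike.
    """

    ECG = "ECG"
    CARDIAC_ENZYME = "CARDIAC_ENZYME"
    CAG = "CAG"
    PCI = "PCI"
    CABG = "CABG"
    BRAIN_IMAGING = "BRAIN_IMAGING"
    STROKE_INTERVENTION = "STROKE_INTERVENTION"


class HospitalType(str, enum.Enum):
    """Hospital tier; ordering for "highest level" is tertiary > secondary > primary."""

    TERTIARY = "tertiary"
    SECONDARY = "secondary"
    PRIMARY = "primary"

    @property
    def level(self) -> int:
        return _HOSPITAL_LEVEL[self]


_HOSPITAL_LEVEL = {
    HospitalType.PRIMARY: 1,
    HospitalType.SECONDARY: 2,
    HospitalType.TERTIARY: 3,
}


class CodeScope(str, enum.Enum):
    """Diagnosis-position scope for code-group matching."""

    PRIMARY_ONLY = "primary_only"
    SECONDARY_OR_LOWER = "secondary_or_lower"
    ANY = "any"


#: ICD-10 three-character code groups for each disease stream.
AMI_CODES: FrozenSet[str] = frozenset({"I21", "I22", "I23"})
STROKE_CODES: FrozenSet[str] = frozenset({"I60", "I61", "I63", "I64"})
DISEASE_CODES = {Disease.AMI: AMI_CODES, Disease.STROKE: STROKE_CODES}


@dataclass(frozen=True)
class DiagnosisEntry:
    """One diagnosis code on a claim with its listed position (1 = primary)."""

    code: str
    position: int

    def __post_init__(self) -> None:
        if not self.code or not _CODE_RE.match(self.code):
            raise ValueError(f"invalid ICD-10 code: {self.code!r}")
        if self.position < 1:
            raise ValueError(f"diagnosis position must be >= 1, got {self.position}")

    @property
    def prefix(self) -> str:
        """Three-character code group, e.g. 'I21.9' -> 'I21'."""
        return self.code[:3]


@dataclass(frozen=True)
class Claim:
    """One insurance claim."""

    claim_id: str
    patient_id: str
    hospital_id: str
    hospital_type: HospitalType
    start_date: datetime.date
    end_date: datetime.date
    diagnoses: tuple
    evidence: FrozenSet[EvidenceFlag] = frozenset()

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"claim {self.claim_id}: start_date {self.start_date} after "
                f"end_date {self.end_date}"
            )
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        object.__setattr__(self, "evidence", frozenset(self.evidence))
        positions = [d.position for d in self.diagnoses]
        if len(positions) != len(set(positions)):
            raise ValueError(f"claim {self.claim_id}: duplicate diagnosis positions")


def claim_sort_key(claim: Claim):
    """Total, deterministic ordering key for claims."""
    return (claim.start_date, claim.end_date, claim.claim_id)


@dataclass
class PatientRecord:
    """All claims of one patient plus the optional death date."""

    patient_id: str
    claims: List[Claim] = field(default_factory=list)
    death_date: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        for c in self.claims:
            if c.patient_id != self.patient_id:
                raise ValueError(
                    f"claim {c.claim_id} belongs to {c.patient_id}, "
                    f"not {self.patient_id}"
                )
        if self.death_date is not None:
            for c in self.claims:
                if c.start_date > self.death_date:
                    raise ValueError(
                        f"claim {c.claim_id} starts after death date "
                        f"{self.death_date}"
                    )
        self.claims = sorted(self.claims, key=claim_sort_key)


def matches_code_group(
    diagnoses: Sequence[DiagnosisEntry],
    group: Iterable[str],
    scope: CodeScope = CodeScope.ANY,
) -> bool:
    """True iff some diagnosis matches the 3-character prefix group at the scope.

    ``group`` is a set of 3-character ICD-10 prefixes (e.g. ``{"I21", "I22"}``);
    subcodes match by prefix, so "I21.9" and "I219" both match "I21".
    Scope ``primary_only`` restricts to position 1, ``secondary_or_lower`` to
    position >= 2, ``any`` to either.
    """
    group = frozenset(group)
    if not group:
        raise ValueError("code group must be non-empty")
    scope = CodeScope(scope)
    for d in diagnoses:
        if d.prefix not in group:
            continue
        if scope is CodeScope.PRIMARY_ONLY and d.position != 1:
            continue
        if scope is CodeScope.SECONDARY_OR_LOWER and d.position < 2:
            continue
        return True
    return False
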