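"""Bundled example data: chart-review counts from a nationwide validation
of claims-based AMI and stroke identification in Korea.

``REVIEW_COUNTS_BY_HOSPITAL`` gives the number of algorithm-identified
events sampled for medical-record review at each of 24 hospitals (5
tertiary, 10 secondary, 9 primary), per disease.  ``ADJUDICATION_COUNTS``
gives, per (disease, event kind, hospital tier), the number of reviewed
events adjudicated as true cases and the number examined — the inputs from
which stratified PPVs and their confidence intervals are computed.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .core import Disease, HospitalType
from .rules import EventKind

__all__ = ["REVIEW_COUNTS_BY_HOSPITAL", "ADJUDICATION_COUNTS"]

# (hospital label, tier, AMI cases reviewed, stroke cases reviewed)
REVIEW_COUNTS_BY_HOSPITAL: List[Tuple[str, HospitalType, int, int]] = [
    ("A", HospitalType.TERTIARY, 421, 428),
    ("B", HospitalType.TERTIARY, 20, 20),
    ("C", HospitalType.TERTIARY, 108, 103),
    ("D", HospitalType.TERTIARY, 86, 89),
    ("E", HospitalType.TERTIARY, 90, 90),
    ("F", HospitalType.SECONDARY, 90, 99),
    ("G", HospitalType.SECONDARY, 40, 36),
    ("H", HospitalType.SECONDARY, 39, 41),
    ("I", HospitalType.SECONDARY, 41, 33),
    ("J", HospitalType.SECONDARY, 40, 40),
    ("K", HospitalType.SECONDARY, 120, 118),
    ("L", HospitalType.SECONDARY, 30, 28),
    ("M", HospitalType.SECONDARY, 49, 45),
    ("N", HospitalType.SECONDARY, 70, 59),
    ("O", HospitalType.SECONDARY, 33, 30),
    ("P", HospitalType.PRIMARY, 3, 17),
    ("Q", HospitalType.PRIMARY, 17, 140),
    ("R", HospitalType.PRIMARY, 23, 36),
    ("S", HospitalType.PRIMARY, 31, 18),
    ("T", HospitalType.PRIMARY, 12, 168),
    ("U", HospitalType.PRIMARY, 17, 22),
    ("V", HospitalType.PRIMARY, 7, 32),
    ("W", HospitalType.PRIMARY, 2, 21),
    ("X", HospitalType.PRIMARY, 10, 28),
]

# (disease, kind, tier) -> (adjudicated true, identified/examined)
ADJUDICATION_COUNTS: Dict[Tuple[Disease, EventKind, HospitalType], Tuple[int, int]] = {
    (Disease.AMI, EventKind.FIRST, HospitalType.TERTIARY): (584, 617),
    (Disease.AMI, EventKind.FIRST, HospitalType.SECONDARY): (339, 368),
    (Disease.AMI, EventKind.FIRST, HospitalType.PRIMARY): (51, 121),
    (Disease.AMI, EventKind.RECURRENT, HospitalType.TERTIARY): (88, 108),
    (Disease.AMI, EventKind.RECURRENT, HospitalType.SECONDARY): (138, 184),
    (Disease.AMI, EventKind.RECURRENT, HospitalType.PRIMARY): (0, 1),
    (Disease.STROKE, EventKind.FIRST, HospitalType.TERTIARY): (458, 549),
    (Disease.STROKE, EventKind.FIRST, HospitalType.SECONDARY): (335, 356),
    (Disease.STROKE, EventKind.FIRST, HospitalType.PRIMARY): (275, 392),
    (Disease.STROKE, EventKind.RECURRENT, HospitalType.TERTIARY): (137, 181),
    (Disease.STROKE, EventKind.RECURRENT, HospitalType.SECONDARY): (154, 173),
    (Disease.STROKE, EventKind.RECURRENT, HospitalType.PRIMARY): (57, 90),
}
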