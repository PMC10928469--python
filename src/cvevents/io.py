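"""CSV readers and writers for the claims, deaths, episodes, events and
adjudication tables.

Claims schema (one row per claim): ``claim_id, patient_id, hospital_id,
hospital_type, start_date, end_date, dx_codes, evidence``.  ``dx_codes`` is
a semicolon-separated list whose order defines the diagnosis position
(first = primary); ``evidence`` is a semicolon-separated list of evidence
flag names, or of raw service codes if a service-code mapping is supplied.
Dates are ISO-8601.  Deaths schema: ``patient_id, death_date``.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    Claim,
    DiagnosisEntry,
    EvidenceFlag,
    HospitalType,
    PatientRecord,
)
from .episodes import Episode
from .rules import EventKind
from .validation import AdjudicationRecord
from .core import Disease

__all__ = [
    "SchemaError",
    "IngestError",
    "CLAIMS_COLUMNS",
    "read_claims",
    "write_claims",
    "read_deaths",
    "write_deaths",
    "read_service_map",
    "episodes_to_frame",
    "write_episodes",
    "read_adjudications",
    "write_adjudications",
]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class IngestError(ValueError):
    """A row could not be parsed (bad date, unmapped service code, ...)."""


CLAIMS_COLUMNS = [
    "claim_id",
    "patient_id",
    "hospital_id",
    "hospital_type",
    "start_date",
    "end_date",
    "dx_codes",
    "evidence",
]
DEATHS_COLUMNS = ["patient_id", "death_date"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_date(value: str, path, line: int, column: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise IngestError(f"{path}, line {line}: bad {column} {value!r}") from exc


def _parse_evidence(
    raw: str,
    service_map: Optional[Mapping[str, EvidenceFlag]],
    strict: bool,
    path,
    line: int,
) -> frozenset:
    flags = set()
    for token in str(raw).split(";"):
        token = token.strip()
        if not token:
            continue
        if token in EvidenceFlag.__members__:
            flags.add(EvidenceFlag[token])
        elif service_map is not None and token in service_map:
            flags.add(service_map[token])
        elif strict:
            raise IngestError(f"{path}, line {line}: unmapped service code {token!r}")
    return frozenset(flags)


def read_claims(
    path,
    service_map: Optional[Mapping[str, EvidenceFlag]] = None,
    deaths: Optional[Mapping[str, datetime.date]] = None,
    strict: bool = True,
) -> List[PatientRecord]:
    """Read a claims CSV into per-patient records, claims sorted by
    (start_date, end_date, claim_id).

    ``deaths`` maps patient_id to death date (see :func:`read_deaths`).
    Under ``strict`` ingest, an evidence token that is neither a flag name
    nor a mapped service code raises :class:`IngestError`; otherwise it is
    dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CLAIMS_COLUMNS, path)
    by_patient: Dict[str, List[Claim]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            htype = HospitalType(row.hospital_type.strip().lower())
        except ValueError as exc:
            raise IngestError(
                f"{path}, line {line}: unknown hospital_type {row.hospital_type!r}"
            ) from exc
        codes = [c.strip() for c in str(row.dx_codes).split(";") if c.strip()]
        if not codes:
            raise IngestError(f"{path}, line {line}: claim has no diagnosis codes")
        try:
            diagnoses = tuple(
                DiagnosisEntry(code=c, position=p) for p, c in enumerate(codes, 1)
            )
        except ValueError as exc:
            raise IngestError(f"{path}, line {line}: {exc}") from exc
        claim = Claim(
            claim_id=row.claim_id,
            patient_id=row.patient_id,
            hospital_id=row.hospital_id,
            hospital_type=htype,
            start_date=_parse_date(row.start_date, path, line, "start_date"),
            end_date=_parse_date(row.end_date, path, line, "end_date"),
            diagnoses=diagnoses,
            evidence=_parse_evidence(row.evidence, service_map, strict, path, line),
        )
        by_patient.setdefault(claim.patient_id, []).append(claim)
    deaths = deaths or {}
    return [
        PatientRecord(pid, claims, death_date=deaths.get(pid))
        for pid, claims in by_patient.items()
    ]


def write_claims(patients: Iterable[PatientRecord], path) -> None:
    """Write patients back to the claims CSV schema (inverse of read_claims)."""
    rows = []
    for p in patients:
        for c in p.claims:
            ordered = sorted(c.diagnoses, key=lambda d: d.position)
            rows.append(
                {
                    "claim_id": c.claim_id,
                    "patient_id": c.patient_id,
                    "hospital_id": c.hospital_id,
                    "hospital_type": c.hospital_type.value,
                    "start_date": c.start_date.isoformat(),
                    "end_date": c.end_date.isoformat(),
                    "dx_codes": ";".join(d.code for d in ordered),
                    "evidence": ";".join(sorted(f.value for f in c.evidence)),
                }
            )
    pd.DataFrame(rows, columns=CLAIMS_COLUMNS).to_csv(path, index=False)


def read_deaths(path) -> Dict[str, datetime.date]:
    """Read the deaths CSV into {patient_id: death_date}."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DEATHS_COLUMNS, path)
    out: Dict[str, datetime.date] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        out[row.patient_id] = _parse_date(row.death_date, path, i + 2, "death_date")
    return out


def write_deaths(deaths: Mapping[str, datetime.date], path) -> None:
    pd.DataFrame(
        [{"patient_id": k, "death_date": v.isoformat()} for k, v in deaths.items()],
        columns=DEATHS_COLUMNS,
    ).to_csv(path, index=False)


def read_service_map(path) -> Dict[str, EvidenceFlag]:
    """Read the two-column raw_code -> evidence flag mapping file."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["raw_code", "evidence_flag"], path)
    out: Dict[str, EvidenceFlag] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        name = row.evidence_flag.strip()
        if name not in EvidenceFlag.__members__:
            raise IngestError(
                f"{path}, line {i + 2}: unknown evidence flag {name!r}"
            )
        out[row.raw_code.strip()] = EvidenceFlag[name]
    return out


def episodes_to_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Tabulate episodes (one row each) with their aggregate fields."""
    rows = [
        {
            "patient_id": e.patient_id,
            "disease": e.disease.value,
            "episode_index": e.episode_index,
            "episode_start": e.episode_start.isoformat(),
            "episode_end": e.episode_end.isoformat(),
            "episode_length_days": e.episode_length_days,
            "n_claims": len(e.claims),
            "in_episode_death": e.in_episode_death,
            "evidence_union": ";".join(sorted(f.value for f in e.evidence_union)),
            "dx_primary_groups": ";".join(sorted(e.dx_primary_groups)),
            "dx_secondary_groups": ";".join(sorted(e.dx_secondary_groups)),
            "first_visit_hospital_type": e.first_visit_hospital_type.value,
            "highest_level_hospital_type": e.highest_level_hospital_type.value,
            "member_claim_ids": ";".join(c.claim_id for c in e.claims),
        }
        for e in episodes
    ]
    columns = [
        "patient_id",
        "disease",
        "episode_index",
        "episode_start",
        "episode_end",
        "episode_length_days",
        "n_claims",
        "in_episode_death",
        "evidence_union",
        "dx_primary_groups",
        "dx_secondary_groups",
        "first_visit_hospital_type",
        "highest_level_hospital_type",
        "member_claim_ids",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_episodes(episodes: Iterable[Episode], path) -> None:
    episodes_to_frame(episodes).to_csv(path, index=False)


ADJUDICATION_COLUMNS = [
    "patient_id",
    "disease",
    "kind",
    "episode_index",
    "hospital_type_first_visit",
    "hospital_type_highest",
    "adjudicated_true",
]


def read_adjudications(path) -> List[AdjudicationRecord]:
    """Read a chart-review adjudication CSV (adjudicated_true coded 0/1)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ADJUDICATION_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            out.append(
                AdjudicationRecord(
                    patient_id=row.patient_id,
                    disease=Disease(row.disease),
                    kind=EventKind(row.kind),
                    episode_index=int(row.episode_index),
                    hospital_type_first_visit=HospitalType(
                        row.hospital_type_first_visit.strip().lower()
                    ),
                    hospital_type_highest=HospitalType(
                        row.hospital_type_highest.strip().lower()
                    ),
                    adjudicated_true=row.adjudicated_true.strip() in ("1", "true", "True"),
                )
            )
        except ValueError as exc:
            raise IngestError(f"{path}, line {line}: {exc}") from exc
    return out


def write_adjudications(records: Iterable[AdjudicationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "disease": r.disease.value,
                "kind": r.kind.value,
                "episode_index": r.episode_index,
                "hospital_type_first_visit": r.hospital_type_first_visit.value,
                "hospital_type_highest": r.hospital_type_highest.value,
                "adjudicated_true": int(r.adjudicated_true),
            }
            for r in records
        ],
        columns=ADJUDICATION_COLUMNS,
    ).to_csv(path, index=False)
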