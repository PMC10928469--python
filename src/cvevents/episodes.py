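"""Hospitalization-episode construction.

A hospitalization episode is the period covered by the consecutive claims
that can reasonably be attributed to a single disease event.  Claims data
fragments single events in two ways the grouping must absorb: long stays are
billed in distinct ~30-day claims, and early complication readmissions file
new claims for the same event.  Scanning a patient's disease-coded claims in
chronological order, a claim starts a NEW episode only when BOTH hold
against the episode under construction:

1. its start date is more than ``gap_days`` (default 28) days after the
   start date of the previously appended claim, and
2. its start date is at least ``interval_days`` (default 3) days after the
   latest end date seen so far in the episode.

Consecutive 30-day billing fragments fail condition 2; late readmissions
for a new event satisfy both.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence

from .core import (
    DISEASE_CODES,
    Claim,
    CodeScope,
    Disease,
    EvidenceFlag,
    HospitalType,
    PatientRecord,
    claim_sort_key,
    matches_code_group,
)

__all__ = ["EpisodeConfig", "Episode", "select_disease_claims", "group_claims", "build_patient_episodes"]


@dataclass(frozen=True)
class EpisodeConfig:
    """Tunable thresholds of the episode-splitting rule.

    gap_days
        Split condition 1: start-to-start gap strictly greater than this
        (days).  Default 28.
    interval_days
        Split condition 2: discharge-to-admission interval at least this
        (days).  Default 3.
    strict_pairwise
        If True, condition 2 compares against the immediately preceding
        claim's end date instead of the running maximum end date over the
        episode (sensitivity-analysis mode; the running maximum is the
        conservative default for overlapping/nested claims).
    """

    gap_days: int = 28
    interval_days: int = 3
    strict_pairwise: bool = False


@dataclass
class Episode:
    """A merged group of claims attributed to one disease event."""

    patient_id: str
    disease: Disease
    claims: List[Claim]
    episode_index: int = 0
    in_episode_death: bool = False

    def __post_init__(self) -> None:
        if not self.claims:
            raise ValueError("episode must contain at least one claim")
        self.claims = sorted(self.claims, key=claim_sort_key)

    @property
    def episode_start(self) -> datetime.date:
        return min(c.start_date for c in self.claims)

    @property
    def episode_end(self) -> datetime.date:
        return max(c.end_date for c in self.claims)

    @property
    def episode_length_days(self) -> int:
        """Inclusive day count: same-day admission and discharge is 1 day."""
        return (self.episode_end - self.episode_start).days + 1

    @property
    def evidence_union(self) -> FrozenSet[EvidenceFlag]:
        out: set = set()
        for c in self.claims:
            out |= c.evidence
        return frozenset(out)

    @property
    def dx_primary_groups(self) -> FrozenSet[str]:
        """3-char prefixes at position 1 on any member claim."""
        return frozenset(
            d.prefix for c in self.claims for d in c.diagnoses if d.position == 1
        )

    @property
    def dx_secondary_groups(self) -> FrozenSet[str]:
        """3-char prefixes at position >= 2 on any member claim."""
        return frozenset(
            d.prefix for c in self.claims for d in c.diagnoses if d.position >= 2
        )

    @property
    def first_visit_hospital_type(self) -> HospitalType:
        return self.claims[0].hospital_type

    @property
    def highest_level_hospital_type(self) -> HospitalType:
        return max((c.hospital_type for c in self.claims), key=lambda t: t.level)


def select_disease_claims(patient: PatientRecord, disease: Disease) -> List[Claim]:
    """Sorted subset of the patient's claims carrying the disease's code group
    at any diagnosis position.

    A claim listing both AMI and stroke codes enters both disease streams.
    """
    group = DISEASE_CODES[Disease(disease)]
    return [
        c
        for c in sorted(patient.claims, key=claim_sort_key)
        if matches_code_group(c.diagnoses, group, CodeScope.ANY)
    ]


def group_claims(
    claims: Sequence[Claim],
    disease: Disease,
    death_date: Optional[datetime.date] = None,
    config: EpisodeConfig = EpisodeConfig(),
) -> List[Episode]:
    """Partition one patient's sorted disease-stream claims into episodes.

    Raises ``ValueError`` on unsorted input or claims from multiple patients.
    """
    claims = list(claims)
    if not claims:
        return []
    patient_ids = {c.patient_id for c in claims}
    if len(patient_ids) > 1:
        raise ValueError(f"claims from multiple patients: {sorted(patient_ids)}")
    keys = [claim_sort_key(c) for c in claims]
    if keys != sorted(keys):
        raise ValueError("claims must be sorted by (start_date, end_date, claim_id)")

    episodes: List[List[Claim]] = [[claims[0]]]
    max_end = claims[0].end_date
    for b in claims[1:]:
        a = episodes[-1][-1]
        ref_end = a.end_date if config.strict_pairwise else max_end
        split = (b.start_date - a.start_date).days > config.gap_days and (
            b.start_date - ref_end
        ).days >= config.interval_days
        if split:
            episodes.append([b])
            max_end = b.end_date
        else:
            episodes[-1].append(b)
            max_end = max(max_end, b.end_date)

    out: List[Episode] = []
    for i, members in enumerate(episodes):
        ep = Episode(
            patient_id=claims[0].patient_id,
            disease=Disease(disease),
            claims=members,
            episode_index=i,
        )
        ep.in_episode_death = (
            death_date is not None and ep.episode_start <= death_date <= ep.episode_end
        )
        out.append(ep)
    return out


def build_patient_episodes(
    patient: PatientRecord,
    disease: Disease,
    config: EpisodeConfig = EpisodeConfig(),
) -> List[Episode]:
    """select_disease_claims followed by group_claims for one patient."""
    stream = select_disease_claims(patient, disease)
    return group_claims(stream, disease, patient.death_date, config)
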