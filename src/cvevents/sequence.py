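"""Chronological first/recurrent event sequencing.

The first event of a disease for a patient is the earliest hospitalization
episode that satisfies the first-event algorithm; every later episode is
tested against the (stricter) recurrent-event algorithm only.  Episodes
before the first qualifying one emit nothing and do not block later
detection; episodes after the first that fail the recurrent criteria emit
nothing even if they would have satisfied the first-event criteria.
The AMI and stroke streams are fully independent.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import pandas as pd

from .core import Disease, PatientRecord
from .episodes import Episode, EpisodeConfig, build_patient_episodes
from .rules import EventCall, EventKind, RuleConfig, classify_episode

__all__ = ["sequence_patient", "sequence_cohort", "events_to_frame"]


def sequence_patient(
    episodes: Sequence[Episode], rule_config: RuleConfig = RuleConfig()
) -> List[EventCall]:
    """Scan one patient's episodes (one disease stream) in order and emit
    first/recurrent event calls.

    Episodes must be sorted by (episode_start, episode_end); all must belong
    to the same patient and disease.
    """
    episodes = list(episodes)
    if not episodes:
        return []
    if len({e.patient_id for e in episodes}) > 1:
        raise ValueError("episodes from multiple patients")
    if len({e.disease for e in episodes}) > 1:
        raise ValueError("episodes from multiple disease streams")
    keys = [(e.episode_start, e.episode_end) for e in episodes]
    if keys != sorted(keys):
        raise ValueError("episodes must be sorted by (episode_start, episode_end)")

    calls: List[EventCall] = []
    have_first = False
    for ep in episodes:
        kind = EventKind.RECURRENT if have_first else EventKind.FIRST
        branch = classify_episode(ep, kind, rule_config)
        if branch is None:
            continue
        calls.append(
            EventCall(
                patient_id=ep.patient_id,
                disease=ep.disease,
                kind=kind,
                episode_index=ep.episode_index,
                rule_branch=branch,
                event_date=ep.episode_start,
                first_visit_hospital_type=ep.first_visit_hospital_type,
                highest_level_hospital_type=ep.highest_level_hospital_type,
            )
        )
        if kind is EventKind.FIRST:
            have_first = True
    return calls


def sequence_cohort(
    patients: Iterable[PatientRecord],
    diseases: Sequence[Disease] = (Disease.AMI, Disease.STROKE),
    episode_config: EpisodeConfig = EpisodeConfig(),
    rule_config: RuleConfig = RuleConfig(),
) -> dict:
    """Run select -> group -> sequence for each patient and disease.

    Returns ``{disease: list of EventCall}``; deterministic given input order
    (and independent of it up to reordering of calls between patients, since
    streams never interact across patients).
    """
    out = {Disease(d): [] for d in diseases}
    for patient in patients:
        for disease in out:
            episodes = build_patient_episodes(patient, disease, episode_config)
            out[disease].extend(sequence_patient(episodes, rule_config))
    return out


def events_to_frame(calls: Iterable[EventCall]) -> pd.DataFrame:
    """Tabulate event calls (one row per identified event)."""
    rows = [
        {
            "patient_id": c.patient_id,
            "disease": c.disease.value,
            "kind": c.kind.value,
            "episode_index": c.episode_index,
            "event_date": c.event_date.isoformat(),
            "rule_branch": c.rule_branch.value,
            "first_visit_hospital_type": c.first_visit_hospital_type.value
            if c.first_visit_hospital_type
            else "",
            "highest_level_hospital_type": c.highest_level_hospital_type.value
            if c.highest_level_hospital_type
            else "",
        }
        for c in calls
    ]
    columns = [
        "patient_id",
        "disease",
        "kind",
        "episode_index",
        "event_date",
        "rule_branch",
        "first_visit_hospital_type",
        "highest_level_hospital_type",
    ]
    return pd.DataFrame(rows, columns=columns)
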