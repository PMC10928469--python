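"""Rule engine classifying hospitalization episodes as AMI/stroke events.

Each identification algorithm is a short ordered list of branches.  A branch
has a code-placement precondition (which ICD-10 groups must occupy the
primary vs secondary-or-lower diagnosis positions of the episode) and a
boolean criterion over the episode's procedure evidence, length, and
in-episode death.  Branches are evaluated top to bottom: the first branch
whose code precondition holds is the only one whose criterion is applied —
the "(-)" entries of the published row preconditions are realized by this
else-ordering, so at most one branch can fire per episode.

First-event algorithms are permissive (a primary-position AMI code plus any
of ECG / cardiac enzymes / CAG / PCI / CABG, or an in-episode death standing
in for type 3 MI).  Recurrent-event algorithms are deliberately stricter —
diagnosis codes are routinely carried over to later, unrelated visits, so a
confirmatory intervention and a minimum stay are demanded instead.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from typing import Callable, FrozenSet, List, Optional, Tuple

from .core import Disease, EvidenceFlag, HospitalType
from .episodes import Episode

__all__ = [
    "EventKind",
    "RuleBranch",
    "RuleConfig",
    "EventCall",
    "ami_first",
    "ami_recurrent",
    "stroke_first",
    "stroke_recurrent",
    "classify_episode",
]


class EventKind(str, enum.Enum):
    FIRST = "FIRST"
    RECURRENT = "RECURRENT"


class RuleBranch(str, enum.Enum):
    """Identifies which algorithm row fired for an episode."""

    AMI_F1 = "AMI_F1"  # primary I21-I23 + broad evidence or death
    AMI_F2 = "AMI_F2"  # secondary-only I21-I23 + CAG/PCI/CABG
    AMI_R = "AMI_R"  # any-position I21-I23 + PCI/CABG + (length>=3 or death)
    STROKE_F1 = "STROKE_F1"  # primary I63-I64
    STROKE_F2 = "STROKE_F2"  # any-position I60-I61 (no primary I63-I64)
    STROKE_F3 = "STROKE_F3"  # secondary-only I63-I64
    STROKE_R1 = "STROKE_R1"  # primary I63-I64
    STROKE_R2 = "STROKE_R2"  # primary I60-I61 (no primary I63-I64)
    STROKE_R3 = "STROKE_R3"  # secondary-only stroke codes

    @property
    def disease(self) -> Disease:
        return Disease.AMI if self.name.startswith("AMI") else Disease.STROKE

    @property
    def kind(self) -> EventKind:
        return EventKind.RECURRENT if "_R" in self.name else EventKind.FIRST


@dataclass(frozen=True)
class RuleConfig:
    """Tunables of the rule engine.

    min_episode_length_days
        The "episode length >= 3 days" arm of the criteria.  Default 3.
    first_claim_positions_only
        If True, code placement (primary vs secondary) is read from the
        episode's first member claim only, instead of aggregating positions
        over all member claims.  Episode-level aggregation is the default
        because split billing fragments of one stay may code the admission
        differently.
    """

    min_episode_length_days: int = 3
    first_claim_positions_only: bool = False


_AMI = frozenset({"I21", "I22", "I23"})
_ISCHEMIC = frozenset({"I63", "I64"})
_HEMORRHAGIC = frozenset({"I60", "I61"})
_STROKE = _ISCHEMIC | _HEMORRHAGIC

_AMI_FIRST_EVIDENCE = frozenset(
    {
        EvidenceFlag.ECG,
        EvidenceFlag.CARDIAC_ENZYME,
        EvidenceFlag.CAG,
        EvidenceFlag.PCI,
        EvidenceFlag.CABG,
    }
)
_AMI_CONFIRMATORY = frozenset({EvidenceFlag.CAG, EvidenceFlag.PCI, EvidenceFlag.CABG})
_AMI_INTERVENTION = frozenset({EvidenceFlag.PCI, EvidenceFlag.CABG})

# A branch precondition looks at (primary groups, secondary-or-lower groups);
# a criterion looks at (evidence union, episode length satisfied?, death).
_Pre = Callable[[FrozenSet[str], FrozenSet[str]], bool]
_Crit = Callable[[FrozenSet[EvidenceFlag], bool, bool], bool]


def _stroke_first_broad(ev: FrozenSet[EvidenceFlag], long: bool, death: bool) -> bool:
    # (brain imaging and [length ok or death]) or intervention or death
    return (
        (EvidenceFlag.BRAIN_IMAGING in ev and (long or death))
        or EvidenceFlag.STROKE_INTERVENTION in ev
        or death
    )


def _stroke_intervention_strict(
    ev: FrozenSet[EvidenceFlag], long: bool, death: bool
) -> bool:
    # intervention and (length ok or death)
    return EvidenceFlag.STROKE_INTERVENTION in ev and (long or death)


def _stroke_recurrent_primary(
    ev: FrozenSet[EvidenceFlag], long: bool, death: bool
) -> bool:
    # (brain imaging or intervention) and (length ok or death)
    return (
        bool(ev & {EvidenceFlag.BRAIN_IMAGING, EvidenceFlag.STROKE_INTERVENTION})
        and (long or death)
    )


_BRANCHES: List[Tuple[RuleBranch, _Pre, _Crit]] = [
    (
        RuleBranch.AMI_F1,
        lambda p, s: bool(p & _AMI),
        lambda ev, long, death: bool(ev & _AMI_FIRST_EVIDENCE) or death,
    ),
    (
        RuleBranch.AMI_F2,
        lambda p, s: bool(s & _AMI),
        lambda ev, long, death: bool(ev & _AMI_CONFIRMATORY),
    ),
    (
        RuleBranch.AMI_R,
        lambda p, s: bool((p | s) & _AMI),
        lambda ev, long, death: bool(ev & _AMI_INTERVENTION) and (long or death),
    ),
    (RuleBranch.STROKE_F1, lambda p, s: bool(p & _ISCHEMIC), _stroke_first_broad),
    (
        RuleBranch.STROKE_F2,
        lambda p, s: bool((p | s) & _HEMORRHAGIC),
        _stroke_first_broad,
    ),
    (
        RuleBranch.STROKE_F3,
        lambda p, s: bool(s & _ISCHEMIC),
        _stroke_intervention_strict,
    ),
    (RuleBranch.STROKE_R1, lambda p, s: bool(p & _ISCHEMIC), _stroke_recurrent_primary),
    (
        RuleBranch.STROKE_R2,
        lambda p, s: bool(p & _HEMORRHAGIC),
        _stroke_recurrent_primary,
    ),
    (
        RuleBranch.STROKE_R3,
        lambda p, s: bool(s & _STROKE),
        _stroke_intervention_strict,
    ),
]


def _episode_positions(
    e: Episode, config: RuleConfig
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    if config.first_claim_positions_only:
        first = e.claims[0]
        prim = frozenset(d.prefix for d in first.diagnoses if d.position == 1)
        sec = frozenset(d.prefix for d in first.diagnoses if d.position >= 2)
        return prim, sec
    return e.dx_primary_groups, e.dx_secondary_groups


def _evaluate(
    e: Episode,
    disease: Disease,
    kind: EventKind,
    config: RuleConfig,
) -> Optional[RuleBranch]:
    if e.disease != disease:
        raise ValueError(f"episode disease {e.disease} does not match {disease}")
    prim, sec = _episode_positions(e, config)
    long_enough = e.episode_length_days >= config.min_episode_length_days
    ev = e.evidence_union
    death = e.in_episode_death
    for branch, pre, crit in _BRANCHES:
        if branch.disease != disease or branch.kind != kind:
            continue
        if pre(prim, sec):
            return branch if crit(ev, long_enough, death) else None
    return None


def ami_first(e: Episode, config: RuleConfig = RuleConfig()) -> Optional[RuleBranch]:
    """First-AMI algorithm; returns the fired branch or None."""
    return _evaluate(e, Disease.AMI, EventKind.FIRST, config)


def ami_recurrent(e: Episode, config: RuleConfig = RuleConfig()) -> Optional[RuleBranch]:
    """Recurrent-AMI algorithm; returns the fired branch or None."""
    return _evaluate(e, Disease.AMI, EventKind.RECURRENT, config)


def stroke_first(e: Episode, config: RuleConfig = RuleConfig()) -> Optional[RuleBranch]:
    """First-stroke algorithm; returns the fired branch or None."""
    return _evaluate(e, Disease.STROKE, EventKind.FIRST, config)


def stroke_recurrent(
    e: Episode, config: RuleConfig = RuleConfig()
) -> Optional[RuleBranch]:
    """Recurrent-stroke algorithm; returns the fired branch or None."""
    return _evaluate(e, Disease.STROKE, EventKind.RECURRENT, config)


def classify_episode(
    e: Episode, kind: EventKind, config: RuleConfig = RuleConfig()
) -> Optional[RuleBranch]:
    """Apply the disease's first- or recurrent-event algorithm to an episode."""
    return _evaluate(e, e.disease, EventKind(kind), config)


@dataclass(frozen=True)
class EventCall:
    """A classified episode: one identified first or recurrent event."""

    patient_id: str
    disease: Disease
    kind: EventKind
    episode_index: int
    rule_branch: RuleBranch
    event_date: datetime.date
    first_visit_hospital_type: Optional[HospitalType] = None
    highest_level_hospital_type: Optional[HospitalType] = None

    def __post_init__(self) -> None:
        if self.rule_branch.disease != self.disease or self.rule_branch.kind != self.kind:
            raise ValueError(
                f"rule branch {self.rule_branch} inconsistent with "
                f"({self.disease}, {self.kind})"
            )
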