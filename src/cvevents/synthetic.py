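"""Synthetic claims cohorts with known ground-truth cardiovascular events.

No public claims corpus accompanies the identification algorithms, so this
module fabricates one with the fragmentation phenomena the episode builder
must absorb and the rule engine must survive:

* long stays billed as consecutive ~30-day claim fragments (next fragment
  starts exactly ``billing_split_period`` days after the previous fragment's
  start, well inside the merge window);
* complication readmissions filed within the merge window (discharge-to-
  admission interval under 3 days), which must fold into the event episode;
* rule-out claims before the first event and carried-over diagnosis codes
  on short, evidence-free visits after an event, which must form their own
  non-qualifying episodes and never surface as events;
* in-hospital deaths, including "type 3 MI"-like presentations that die
  before any procedure is performed.

Each true event targets a specific branch of the identification algorithms
so every table row receives dedicated coverage; uniform random evidence
would starve rare branches.  With the default (canonical) emission settings
every scheduled event emits a fully qualifying pattern, making the
generator's own label log an exact oracle for the pipeline.  Fragment-count
and stay-length distributions are plausible placeholders, not estimates
from real claims data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Claim,
    DiagnosisEntry,
    Disease,
    EvidenceFlag,
    HospitalType,
    PatientRecord,
)
from .rules import EventCall, EventKind, RuleBranch
from .validation import AdjudicationRecord

__all__ = ["GroundTruthEvent", "SimulationConfig", "generate_cohort", "simulate_chart_review"]

BASE_DATE = datetime.date(2011, 1, 1)

_AMI_EVENT_CODES = ["I21.0", "I21.1", "I21.4", "I21.9", "I22.0", "I23.8"]
_ISCHEMIC_CODES = ["I63.9", "I63.5", "I64"]
_HEMORRHAGIC_CODES = ["I60.7", "I61.9"]
# Comorbidity filler; deliberately disjoint from both disease code groups.
_FILLER_CODES = ["I50.9", "I10", "E11.9", "J18.9", "N18.3"]

_FIRST_BRANCHES = {
    Disease.AMI: [RuleBranch.AMI_F1, RuleBranch.AMI_F2],
    Disease.STROKE: [RuleBranch.STROKE_F1, RuleBranch.STROKE_F2, RuleBranch.STROKE_F3],
}
_RECURRENT_BRANCHES = {
    Disease.AMI: [RuleBranch.AMI_R],
    Disease.STROKE: [RuleBranch.STROKE_R1, RuleBranch.STROKE_R2, RuleBranch.STROKE_R3],
}
# Death alone satisfies these branches' criteria (the "or death" arms).
_DEATH_SUFFICES = {RuleBranch.AMI_F1, RuleBranch.STROKE_F1, RuleBranch.STROKE_F2}


@dataclass(frozen=True)
class GroundTruthEvent:
    """Label-log entry for one scheduled true event."""

    patient_id: str
    disease: Disease
    kind: EventKind
    true_event_date: datetime.date
    expected_detectable: bool
    rule_branch: RuleBranch


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Probabilities are per patient (``p_event``) or per event (the rest);
    ``detect_probability`` maps each rule branch to the chance that a
    scheduled event of that branch emits its fully qualifying pattern —
    the default of 1.0 everywhere is the canonical setting under which the
    label log and the pipeline output must agree exactly.
    """

    n_patients: int = 500
    p_event: Dict[Disease, float] = field(
        default_factory=lambda: {Disease.AMI: 0.35, Disease.STROKE: 0.35}
    )
    p_recurrent: float = 0.30
    billing_split_period: int = 30
    p_long_stay: float = 0.25
    p_readmission: float = 0.30
    p_carryover: float = 0.40
    p_ruleout: float = 0.20
    p_death: float = 0.08
    p_death_only: float = 0.30
    first_branch_weights: Dict[Disease, Sequence[float]] = field(
        default_factory=lambda: {Disease.AMI: (0.8, 0.2), Disease.STROKE: (0.6, 0.25, 0.15)}
    )
    recurrent_branch_weights: Dict[Disease, Sequence[float]] = field(
        default_factory=lambda: {Disease.AMI: (1.0,), Disease.STROKE: (0.5, 0.25, 0.25)}
    )
    detect_probability: Dict[RuleBranch, float] = field(
        default_factory=lambda: {b: 1.0 for b in RuleBranch}
    )
    hospital_mix: Dict[HospitalType, float] = field(
        default_factory=lambda: {
            HospitalType.TERTIARY: 0.35,
            HospitalType.SECONDARY: 0.40,
            HospitalType.PRIMARY: 0.25,
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_recurrent,
            self.p_long_stay,
            self.p_readmission,
            self.p_carryover,
            self.p_ruleout,
            self.p_death,
            self.p_death_only,
            *self.p_event.values(),
            *self.detect_probability.values(),
            *self.hospital_mix.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if self.billing_split_period < 2:
            raise ValueError("billing_split_period must be at least 2 days")


class _Emitter:
    """Builds one patient's claim stream on a single day timeline."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator, pid: str):
        self.cfg = config
        self.rng = rng
        self.pid = pid
        self.claims: List[Claim] = []
        self.seq = 0
        self.death_day: Optional[int] = None

    def _hospital(self) -> Tuple[str, HospitalType]:
        types = list(self.cfg.hospital_mix)
        w = np.array([self.cfg.hospital_mix[t] for t in types], dtype=float)
        htype = types[self.rng.choice(len(types), p=w / w.sum())]
        return f"H-{htype.value[:3]}-{self.rng.integers(1, 6)}", htype

    def _claim(
        self,
        start: int,
        end: int,
        codes: Sequence[Tuple[str, int]],
        evidence: frozenset = frozenset(),
    ) -> Claim:
        self.seq += 1
        hid, htype = self._hospital()
        diagnoses = tuple(DiagnosisEntry(code=c, position=p) for c, p in codes)
        claim = Claim(
            claim_id=f"{self.pid}-C{self.seq:03d}",
            patient_id=self.pid,
            hospital_id=hid,
            hospital_type=htype,
            start_date=BASE_DATE + datetime.timedelta(days=int(start)),
            end_date=BASE_DATE + datetime.timedelta(days=int(end)),
            diagnoses=diagnoses,
            evidence=frozenset(evidence),
        )
        self.claims.append(claim)
        return claim

    # -- code placement ----------------------------------------------------
    def _codes_for(self, branch: RuleBranch) -> List[Tuple[str, int]]:
        """Diagnosis list realizing the branch's code-placement precondition."""
        rng = self.rng
        filler = str(rng.choice(_FILLER_CODES))
        if branch in (RuleBranch.AMI_F1,):
            return [(str(rng.choice(_AMI_EVENT_CODES)), 1), (filler, 2)]
        if branch is RuleBranch.AMI_F2:
            return [(filler, 1), (str(rng.choice(_AMI_EVENT_CODES)), 2)]
        if branch is RuleBranch.AMI_R:
            code = str(rng.choice(_AMI_EVENT_CODES))
            return [(code, 1), (filler, 2)] if rng.random() < 0.7 else [(filler, 1), (code, 2)]
        if branch in (RuleBranch.STROKE_F1, RuleBranch.STROKE_R1):
            return [(str(rng.choice(_ISCHEMIC_CODES)), 1), (filler, 2)]
        if branch in (RuleBranch.STROKE_F2, RuleBranch.STROKE_R2):
            code = str(rng.choice(_HEMORRHAGIC_CODES))
            if branch is RuleBranch.STROKE_R2 or rng.random() < 0.7:
                return [(code, 1), (filler, 2)]
            return [(filler, 1), (code, 2)]  # any-position row of the first-event table
        if branch is RuleBranch.STROKE_F3:
            return [(filler, 1), (str(rng.choice(_ISCHEMIC_CODES)), 2)]
        if branch is RuleBranch.STROKE_R3:
            return [(filler, 1), (str(rng.choice(_ISCHEMIC_CODES + _HEMORRHAGIC_CODES)), 2)]
        raise AssertionError(branch)

    # -- evidence / length patterns ---------------------------------------
    def _pattern_for(
        self, branch: RuleBranch, fatal: bool
    ) -> Tuple[frozenset, int, bool]:
        """(evidence, stay length in days, death-only?) for a qualifying event."""
        rng = self.rng
        long_stay = rng.random() < self.cfg.p_long_stay
        needs_length = branch not in (RuleBranch.AMI_F1, RuleBranch.AMI_F2)
        death_only = (
            fatal
            and branch in _DEATH_SUFFICES
            and rng.random() < self.cfg.p_death_only
        )
        if death_only:
            return frozenset(), int(rng.integers(1, 3)), True

        if long_stay:
            length = int(rng.integers(self.cfg.billing_split_period + 5, 75))
        elif needs_length or rng.random() < 0.7:
            length = int(rng.integers(3, 15))
        else:
            length = int(rng.integers(1, 3))

        if branch is RuleBranch.AMI_F1:
            ev = {EvidenceFlag.ECG}
            if rng.random() < 0.8:
                ev.add(EvidenceFlag.CARDIAC_ENZYME)
            if rng.random() < 0.6:
                ev.add(EvidenceFlag.CAG)
            if rng.random() < 0.5:
                ev.add(EvidenceFlag.PCI)
        elif branch is RuleBranch.AMI_F2:
            confirmatory = [EvidenceFlag.CAG, EvidenceFlag.PCI, EvidenceFlag.CABG]
            ev = {confirmatory[rng.choice(3)]}
            if rng.random() < 0.5:
                ev.add(EvidenceFlag.ECG)
        elif branch is RuleBranch.AMI_R:
            ev = {EvidenceFlag.PCI if rng.random() < 0.85 else EvidenceFlag.CABG}
            ev.add(EvidenceFlag.CAG)
        elif branch in (RuleBranch.STROKE_F1, RuleBranch.STROKE_F2):
            if rng.random() < 0.75:
                ev = {EvidenceFlag.BRAIN_IMAGING}
                length = max(length, 3) if not fatal else length
            else:
                ev = {EvidenceFlag.STROKE_INTERVENTION}
                if rng.random() < 0.7:
                    ev.add(EvidenceFlag.BRAIN_IMAGING)
        elif branch in (RuleBranch.STROKE_F3, RuleBranch.STROKE_R3):
            ev = {EvidenceFlag.STROKE_INTERVENTION}
            if not fatal:
                length = max(length, 3)
        else:  # STROKE_R1 / STROKE_R2
            ev = {EvidenceFlag.BRAIN_IMAGING if rng.random() < 0.7 else EvidenceFlag.STROKE_INTERVENTION}
            if not fatal:
                length = max(length, 3)
        if needs_length and not fatal:
            length = max(length, 3)
        return frozenset(ev), length, False

    # -- emission ----------------------------------------------------------
    def emit_event(
        self, branch: RuleBranch, day0: int, fatal: bool
    ) -> Tuple[bool, int, int]:
        """Emit one event's claim cluster starting at ``day0``.

        Returns (detectable, last fragment start day, cluster max end day).
        """
        rng = self.rng
        detectable = rng.random() < self.cfg.detect_probability.get(branch, 1.0)
        evidence, length, death_only = self._pattern_for(branch, fatal)
        if not detectable:
            # Suppress the qualifying pattern entirely: no evidence, short
            # stay, no in-episode death -> fails every branch criterion.
            evidence, length, death_only = frozenset(), int(rng.integers(1, 3)), False
            fatal = False
        codes = self._codes_for(branch)
        end_day = day0 + length - 1

        # 30-day billing-cycle fragments for long stays.
        period = self.cfg.billing_split_period
        fragments: List[Tuple[int, int]] = []
        s = day0
        while end_day - s + 1 > period:
            fragments.append((s, s + period - 1))
            s += period
        fragments.append((s, end_day))

        for i, (fs, fe) in enumerate(fragments):
            ev = evidence if i == 0 else (evidence if rng.random() < 0.3 else frozenset())
            self._claim(fs, fe, codes, ev)
        last_start, max_end = fragments[-1][0], end_day

        # Complication readmission inside the merge window (must fold in).
        if not fatal and not death_only and rng.random() < self.cfg.p_readmission:
            rs = max_end + int(rng.integers(0, 3))
            re_ = rs + int(rng.integers(0, 3))
            self._claim(rs, re_, codes, frozenset())
            last_start, max_end = max(last_start, rs), max(max_end, re_)

        if fatal or death_only:
            self.death_day = max_end
        return detectable, last_start, max_end

    def emit_noise(self, disease: Disease, last_start: int, max_end: int) -> Tuple[int, int]:
        """Short, evidence-free carried-over-code claim in its own episode."""
        pool = _AMI_EVENT_CODES if disease is Disease.AMI else _ISCHEMIC_CODES + _HEMORRHAGIC_CODES
        code = str(self.rng.choice(pool))
        filler = str(self.rng.choice(_FILLER_CODES))
        start = max(max_end + 3, last_start + self.rng.integers(29, 45))
        end = start + int(self.rng.integers(0, 2))
        codes = [(code, 1), (filler, 2)] if self.rng.random() < 0.5 else [(filler, 1), (code, 2)]
        self._claim(int(start), int(end), codes)
        return int(start), int(end)


def generate_cohort(
    config: SimulationConfig,
) -> Tuple[List[PatientRecord], List[GroundTruthEvent]]:
    """Generate a synthetic cohort and its ground-truth event log.

    Byte-identical output for identical config (including ``rng_seed``).
    Under canonical emission settings every ground-truth event is
    ``expected_detectable`` and the pipeline must recover the log exactly.
    """
    rng = np.random.default_rng(config.rng_seed)
    patients: List[PatientRecord] = []
    truth: List[GroundTruthEvent] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        em = _Emitter(config, rng, pid)

        slots: List[Tuple[Disease, EventKind, RuleBranch]] = []
        for disease in (Disease.AMI, Disease.STROKE):
            if rng.random() >= config.p_event.get(disease, 0.0):
                continue
            fb = _FIRST_BRANCHES[disease]
            w = np.array(config.first_branch_weights[disease], dtype=float)
            slots_d = [(disease, EventKind.FIRST, fb[rng.choice(len(fb), p=w / w.sum())])]
            if rng.random() < config.p_recurrent:
                rb = _RECURRENT_BRANCHES[disease]
                wr = np.array(config.recurrent_branch_weights[disease], dtype=float)
                slots_d.append(
                    (disease, EventKind.RECURRENT, rb[rng.choice(len(rb), p=wr / wr.sum())])
                )
            slots.extend(slots_d)
        if not slots:
            patients.append(PatientRecord(pid, [], None))
            continue

        fatal_patient = rng.random() < config.p_death
        day = int(rng.integers(0, 1200))

        # Pre-event rule-out visit: disease-coded, evidence-free, far enough
        # before the first cluster to stay a separate episode.
        if rng.random() < config.p_ruleout:
            ro_start = day - int(rng.integers(35, 90))
            ro_end = ro_start + int(rng.integers(0, 2))
            d0 = slots[0][0]
            pool = _AMI_EVENT_CODES if d0 is Disease.AMI else _ISCHEMIC_CODES
            em._claim(ro_start, ro_end, [(str(rng.choice(pool)), 1)])

        for j, (disease, kind, branch) in enumerate(slots):
            fatal = fatal_patient and j == len(slots) - 1
            detectable, last_start, max_end = em.emit_event(branch, day, fatal)
            truth.append(
                GroundTruthEvent(
                    patient_id=pid,
                    disease=disease,
                    kind=kind,
                    true_event_date=BASE_DATE + datetime.timedelta(days=day),
                    expected_detectable=detectable,
                    rule_branch=branch,
                )
            )
            if em.death_day is None and rng.random() < config.p_carryover:
                n_start, n_end = em.emit_noise(disease, last_start, max_end)
                last_start, max_end = n_start, n_end
            day = int(max(last_start + 29, max_end + 3) + rng.integers(11, 160))

        death_date = (
            BASE_DATE + datetime.timedelta(days=em.death_day)
            if em.death_day is not None
            else None
        )
        patients.append(PatientRecord(pid, em.claims, death_date))
    return patients, truth


def simulate_chart_review(
    events: Sequence[EventCall],
    stratum_true_ppv: Mapping[Tuple[Disease, EventKind, HospitalType], float],
    rng_seed: int,
    stratum_rule: str = "first_visit",
) -> List[AdjudicationRecord]:
    """Adjudicate each identified event true with its stratum's probability.

    ``stratum_true_ppv`` maps (disease, kind, hospital type) to the
    probability (proportion scale) that a reviewed event of that stratum is
    confirmed.  The hospital type used for the lookup follows
    ``stratum_rule`` ("first_visit" or "highest_level").  Unknown strata
    raise ``KeyError``; probabilities outside [0, 1] raise ``ValueError``.
    """
    for key, p in stratum_true_ppv.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for stratum {key} outside [0, 1]: {p}")
    rng = np.random.default_rng(rng_seed)
    out: List[AdjudicationRecord] = []
    for ev in events:
        htype = (
            ev.first_visit_hospital_type
            if stratum_rule == "first_visit"
            else ev.highest_level_hospital_type
        )
        key = (ev.disease, ev.kind, htype)
        if key not in stratum_true_ppv:
            raise KeyError(f"no true PPV configured for stratum {key}")
        out.append(
            AdjudicationRecord(
                patient_id=ev.patient_id,
                disease=ev.disease,
                kind=ev.kind,
                episode_index=ev.episode_index,
                hospital_type_first_visit=ev.first_visit_hospital_type,
                hospital_type_highest=ev.highest_level_hospital_type,
                adjudicated_true=bool(rng.random() < stratum_true_ppv[key]),
            )
        )
    return out
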