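import datetime

import pytest

from cvevents.core import Claim, DiagnosisEntry, EvidenceFlag, HospitalType
from cvevents.episodes import Episode
from cvevents.core import Disease

BASE = datetime.date(2015, 1, 1)


def day(n: int) -> datetime.date:
    return BASE + datetime.timedelta(days=n)


def make_claim(
    start,
    end,
    codes=(("I21.0", 1),),
    evidence=(),
    claim_id=None,
    patient_id="P1",
    hospital_id="H1",
    hospital_type=HospitalType.TERTIARY,
):
    """Claim factory; ``start``/``end`` are day offsets from a fixed base."""
    start_d = day(start) if isinstance(start, int) else start
    end_d = day(end) if isinstance(end, int) else end
    return Claim(
        claim_id=claim_id or f"C-{start_d.isoformat()}-{end_d.isoformat()}",
        patient_id=patient_id,
        hospital_id=hospital_id,
        hospital_type=hospital_type,
        start_date=start_d,
        end_date=end_d,
        diagnoses=tuple(DiagnosisEntry(code=c, position=p) for c, p in codes),
        evidence=frozenset(EvidenceFlag(e) if isinstance(e, str) else e for e in evidence),
    )


def make_episode(
    disease=Disease.AMI,
    primary=("I21",),
    secondary=(),
    evidence=(),
    length=5,
    death=False,
    patient_id="P1",
):
    """Episode with the requested episode-level code placement and evidence.

    Each requested primary group gets its own member claim with that code at
    position 1; all secondary groups share one claim behind a filler primary
    code, so they sit at positions >= 2.  All claims span the same dates.
    """

    def sub(g):
        return g if "." in g else f"{g}.9"

    claims = []
    for i, g in enumerate(primary):
        claims.append(
            make_claim(
                0,
                length - 1,
                codes=((sub(g), 1),),
                claim_id=f"CP{i}",
                patient_id=patient_id,
            )
        )
    sec_codes = [("Z03.5", 1)] + [(sub(g), i + 2) for i, g in enumerate(secondary)]
    claims.append(
        make_claim(
            0, length - 1, codes=tuple(sec_codes), claim_id="CS", patient_id=patient_id
        )
    )
    claims[0] = make_claim(
        0,
        length - 1,
        codes=tuple((d.code, d.position) for d in claims[0].diagnoses),
        evidence=evidence,
        claim_id=claims[0].claim_id,
        patient_id=patient_id,
    )
    ep = Episode(patient_id=patient_id, disease=disease, claims=claims)
    ep.in_episode_death = death
    return ep


@pytest.fixture
def rng():
    import numpy as np

    return np.random.default_rng(20240101)
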