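"""Positive-predictive-value validation statistics.

Algorithm-identified events are validated by chart review: each sampled
event is adjudicated true or false, and the PPV of a stratum is

    PPV = 100 * (events adjudicated true) / (events examined)

with a 95% binomial confidence interval.  Strata are (disease, event kind,
hospital type), with the hospital type of a multi-hospital episode assigned
either by the first hospital visited or by the highest-level hospital
visited.  Stratum PPVs are combined two ways: an unweighted pool (simple
aggregation of counts) and a weighted pool (hospital-type case counts as
weights).

The default interval is the Wald normal approximation, which reproduces the
printed intervals of published claims-validation studies; Wilson is
available as an alternative.  Intervals are truncated to [0, 100].  A
stratum with no identified events, or with a degenerate proportion (0 or 1)
at n = 1, reports "N/A" in place of an interval.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .core import Disease, HospitalType
from .rules import EventKind

__all__ = [
    "CIMethod",
    "PPVResult",
    "AdjudicationRecord",
    "StratumRule",
    "ppv",
    "assign_stratum",
    "weighted_pooled_ppv",
    "unweighted_pooled_ppv",
    "stratified_ppv_table",
    "round_half_up",
]


class CIMethod(str, enum.Enum):
    WALD = "wald"
    WILSON = "wilson"


class StratumRule(str, enum.Enum):
    """How the hospital type of a multi-hospital episode is assigned."""

    FIRST_VISIT = "first_visit"
    HIGHEST_LEVEL = "highest_level"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero on the percentage scale (93.25 -> 93.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PPVResult:
    """PPV of one validation stratum (percent scale).

    ``ppv_percent`` is None when no events were identified; the confidence
    bounds are None whenever the interval is undefined (no events, or a
    degenerate proportion at n = 1).
    """

    stratum: Tuple
    n_adjudicated_true: int
    n_identified: int
    ppv_percent: Optional[float]
    ci_low_percent: Optional[float]
    ci_high_percent: Optional[float]

    def _replace_stratum(self, stratum: Tuple) -> "PPVResult":
        import dataclasses

        return dataclasses.replace(self, stratum=stratum)

    @property
    def is_na(self) -> bool:
        """True when the table cell should display "N/A"."""
        return self.ppv_percent is None or self.ci_low_percent is None

    def display(self, ndigits: int = 1) -> str:
        if self.is_na:
            return "N/A"
        return (
            f"{round_half_up(self.ppv_percent, ndigits)} "
            f"({round_half_up(self.ci_low_percent, ndigits)}, "
            f"{round_half_up(self.ci_high_percent, ndigits)})"
        )


def _interval(
    n_true: int, n: int, confidence: float, method: CIMethod
) -> Tuple[float, float]:
    p = n_true / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if method is CIMethod.WALD:
        half = z * math.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    else:  # Wilson score interval
        denom = 1.0 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = center - half, center + half
    return max(0.0, lo) * 100.0, min(1.0, hi) * 100.0


def ppv(
    n_true: int,
    n_identified: int,
    confidence: float = 0.95,
    method: CIMethod = CIMethod.WALD,
    stratum: Tuple = ("pooled",),
) -> PPVResult:
    """PPV with confidence interval for one stratum's counts.

    ``n_identified = 0`` yields an undefined ("N/A") result; so does a
    degenerate proportion (0/1 or 1/1), where the Wald interval collapses to
    a point with no information.
    """
    if n_true < 0 or n_identified < 0 or n_true > n_identified:
        raise ValueError(
            f"require 0 <= n_true <= n_identified, got {n_true}/{n_identified}"
        )
    if n_identified == 0:
        return PPVResult(stratum, n_true, n_identified, None, None, None)
    value = 100.0 * n_true / n_identified
    if n_identified == 1 and n_true in (0, 1):
        return PPVResult(stratum, n_true, n_identified, value, None, None)
    lo, hi = _interval(n_true, n_identified, confidence, CIMethod(method))
    return PPVResult(stratum, n_true, n_identified, value, lo, hi)


@dataclass(frozen=True)
class AdjudicationRecord:
    """Chart-review outcome for one algorithm-identified event."""

    patient_id: str
    disease: Disease
    kind: EventKind
    episode_index: int
    hospital_type_first_visit: HospitalType
    hospital_type_highest: HospitalType
    adjudicated_true: bool


def assign_stratum(
    rec: AdjudicationRecord, rule: StratumRule = StratumRule.FIRST_VISIT
) -> HospitalType:
    """Hospital-type stratum of a reviewed event under the chosen rule."""
    if StratumRule(rule) is StratumRule.FIRST_VISIT:
        return rec.hospital_type_first_visit
    return rec.hospital_type_highest


def weighted_pooled_ppv(
    stratum_results: Mapping[HospitalType, PPVResult],
    weights: Mapping[HospitalType, float],
    confidence: float = 0.95,
) -> PPVResult:
    """Weight stratum PPVs by hospital-type case counts.

    pooled = sum(w_t * ppv_t) / sum(w_t); the interval combines stratum
    binomial variances as sum(w_t^2 p_t(1-p_t)/n_t) / (sum w_t)^2 (Wald).
    Positive-weight strata with an undefined PPV are dropped with a warning.
    """
    if not weights or all(w <= 0 for w in weights.values()):
        raise ValueError("at least one positive weight required")
    used: List[Tuple[float, PPVResult]] = []
    for htype, w in weights.items():
        if w <= 0:
            continue
        res = stratum_results.get(htype)
        if res is None or res.ppv_percent is None:
            warnings.warn(
                f"dropping stratum {htype} with weight {w}: PPV undefined",
                stacklevel=2,
            )
            continue
        used.append((float(w), res))
    if not used:
        raise ValueError("no weighted stratum has a defined PPV")
    wsum = sum(w for w, _ in used)
    pooled = sum(w * r.ppv_percent for w, r in used) / wsum
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    var = (
        sum(
            (w / wsum) ** 2
            * (r.ppv_percent / 100.0)
            * (1.0 - r.ppv_percent / 100.0)
            / r.n_identified
            for w, r in used
        )
    )
    half = z * math.sqrt(var) * 100.0
    n_true = sum(r.n_adjudicated_true for _, r in used)
    n_id = sum(r.n_identified for _, r in used)
    return PPVResult(
        ("weighted_pooled",),
        n_true,
        n_id,
        pooled,
        max(0.0, pooled - half),
        min(100.0, pooled + half),
    )


def unweighted_pooled_ppv(
    stratum_results: Iterable[PPVResult],
    confidence: float = 0.95,
    method: CIMethod = CIMethod.WALD,
) -> PPVResult:
    """Simple aggregation: PPV over the summed counts of all strata."""
    n_true = n_id = 0
    for r in stratum_results:
        n_true += r.n_adjudicated_true
        n_id += r.n_identified
    res = ppv(n_true, n_id, confidence, method, stratum=("pooled",))
    return res


def stratified_ppv_table(
    adjudications: Sequence[AdjudicationRecord],
    stratum_rule: StratumRule = StratumRule.FIRST_VISIT,
    weights: Optional[Mapping[HospitalType, float]] = None,
    confidence: float = 0.95,
    method: CIMethod = CIMethod.WALD,
) -> pd.DataFrame:
    """Per-(disease, kind, hospital type) PPV table plus pooled rows.

    Mirrors the layout of published validation tables: one row per hospital
    tier with adjudicated/identified counts and PPV (CI), then an unweighted
    pooled row and, if ``weights`` are given, a weighted pooled row.
    """
    rows = []
    tiers = [HospitalType.TERTIARY, HospitalType.SECONDARY, HospitalType.PRIMARY]
    for disease in Disease:
        for kind in EventKind:
            sub = [
                r for r in adjudications if r.disease == disease and r.kind == kind
            ]
            if not sub:
                continue
            per_tier: Dict[HospitalType, PPVResult] = {}
            for tier in tiers:
                members = [r for r in sub if assign_stratum(r, stratum_rule) == tier]
                res = ppv(
                    sum(r.adjudicated_true for r in members),
                    len(members),
                    confidence,
                    method,
                    stratum=(disease.value, kind.value, tier.value),
                )
                per_tier[tier] = res
                rows.append(res)
            rows.append(
                unweighted_pooled_ppv(per_tier.values(), confidence, method)._replace_stratum(
                    (disease.value, kind.value, "pooled")
                )
            )
            if weights is not None:
                rows.append(
                    weighted_pooled_ppv(per_tier, weights, confidence)._replace_stratum(
                        (disease.value, kind.value, "weighted_pooled")
                    )
                )
    return pd.DataFrame(
        {
            "disease": [r.stratum[0] for r in rows],
            "kind": [r.stratum[1] for r in rows],
            "stratum": [r.stratum[2] for r in rows],
            "n_adjudicated_true": [r.n_adjudicated_true for r in rows],
            "n_identified": [r.n_identified for r in rows],
            "ppv_percent": [
                None if r.ppv_percent is None else round_half_up(r.ppv_percent)
                for r in rows
            ],
            "ci_low_percent": [
                None if r.ci_low_percent is None else round_half_up(r.ci_low_percent)
                for r in rows
            ],
            "ci_high_percent": [
                None if r.ci_high_percent is None else round_half_up(r.ci_high_percent)
                for r in rows
            ],
            "display": [r.display() for r in rows],
        }
    )
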