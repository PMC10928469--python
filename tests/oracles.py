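"""Independent reference implementations used to cross-check the package.

These deliberately share no code with ``cvevents``: the code-group matcher
is a brute-force scan, the episode partitioner is an exhaustive consistency
check over all consecutive partitions, and the rule oracle is a literal
nested-if transcription of the published algorithm rows.
"""

from typing import FrozenSet, List, Optional, Sequence, Tuple

AMI = {"I21", "I22", "I23"}
ISCH = {"I63", "I64"}
HEM = {"I60", "I61"}

AMI_FIRST_EV = {"ECG", "CARDIAC_ENZYME", "CAG", "PCI", "CABG"}
AMI_CONFIRM = {"CAG", "PCI", "CABG"}
AMI_INTERV = {"PCI", "CABG"}


def code_match_oracle(
    diagnoses: Sequence[Tuple[str, int]], group: set, scope: str
) -> bool:
    """Brute-force scan over (code, position) pairs."""
    hits = []
    for code, pos in diagnoses:
        if code[:3] in group:
            hits.append(pos)
    if scope == "primary_only":
        return any(p == 1 for p in hits)
    if scope == "secondary_or_lower":
        return any(p >= 2 for p in hits)
    return bool(hits)


def consistent_partitions(
    claims: Sequence[Tuple[int, int]], gap: int = 28, interval: int = 3
) -> List[List[List[Tuple[int, int]]]]:
    """All consecutive partitions of sorted (start, end) day-pairs that are
    consistent with the pairwise split rules.

    A claim B splits from the running episode iff BOTH:
    start(B) - start(previous appended claim) > gap, and
    start(B) - max end so far >= interval.  A partition is consistent when
    every internal claim does NOT split from its within-part prefix and
    every part-boundary claim DOES split from the preceding part.
    """
    n = len(claims)
    results = []
    for mask in range(2 ** max(0, n - 1)):
        parts: List[List[Tuple[int, int]]] = [[claims[0]]] if n else []
        for i in range(1, n):
            if mask >> (i - 1) & 1:
                parts.append([claims[i]])
            else:
                parts[-1].append(claims[i])
        ok = True
        for pi, part in enumerate(parts):
            # boundary claim must split from the previous part
            if pi > 0:
                prev = parts[pi - 1]
                b = part[0]
                splits = (b[0] - prev[-1][0] > gap) and (
                    b[0] - max(c[1] for c in prev) >= interval
                )
                if not splits:
                    ok = False
                    break
            # internal claims must not split from their prefix
            for j in range(1, len(part)):
                b = part[j]
                prefix = part[:j]
                splits = (b[0] - prefix[-1][0] > gap) and (
                    b[0] - max(c[1] for c in prefix) >= interval
                )
                if splits:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            results.append(parts)
    return results


def rule_oracle(
    disease: str,
    kind: str,
    prim: FrozenSet[str],
    sec: FrozenSet[str],
    ev: FrozenSet[str],
    length: int,
    death: bool,
) -> Optional[str]:
    """Literal transcription of the identification-algorithm table rows."""
    long = length >= 3
    if disease == "AMI" and kind == "FIRST":
        if prim & AMI:
            if (ev & AMI_FIRST_EV) or death:
                return "AMI_F1"
            return None
        if sec & AMI:
            if ev & AMI_CONFIRM:
                return "AMI_F2"
            return None
        return None
    if disease == "AMI" and kind == "RECURRENT":
        if (prim | sec) & AMI:
            if (ev & AMI_INTERV) and (long or death):
                return "AMI_R"
            return None
        return None
    if disease == "STROKE" and kind == "FIRST":
        if prim & ISCH:
            if ("BRAIN_IMAGING" in ev and (long or death)) or (
                "STROKE_INTERVENTION" in ev
            ) or death:
                return "STROKE_F1"
            return None
        if (prim | sec) & HEM:
            if ("BRAIN_IMAGING" in ev and (long or death)) or (
                "STROKE_INTERVENTION" in ev
            ) or death:
                return "STROKE_F2"
            return None
        if sec & ISCH:
            if "STROKE_INTERVENTION" in ev and (long or death):
                return "STROKE_F3"
            return None
        return None
    if disease == "STROKE" and kind == "RECURRENT":
        if prim & ISCH:
            if (("BRAIN_IMAGING" in ev) or ("STROKE_INTERVENTION" in ev)) and (
                long or death
            ):
                return "STROKE_R1"
            return None
        if prim & HEM:
            if (("BRAIN_IMAGING" in ev) or ("STROKE_INTERVENTION" in ev)) and (
                long or death
            ):
                return "STROKE_R2"
            return None
        if sec & (ISCH | HEM):
            if "STROKE_INTERVENTION" in ev and (long or death):
                return "STROKE_R3"
            return None
        return None
    raise ValueError((disease, kind))


def wald_ci_oracle(n_true: int, n: int, z: float = 1.959963984540054):
    """Hand-computed Wald interval on the percent scale."""
    p = n_true / n
    half = z * (p * (1 - p) / n) ** 0.5
    return (max(0.0, p - half) * 100.0, min(1.0, p + half) * 100.0)
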