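"""Joint sperm-pair analysis: CNV typing, role assignment, cohort tables.

CNV types over a sperm pair (haploid baseline 1):

* type I  — a fragment lost in one sperm and gained in the other
  (joint states 0/2): fragmentation around the second pollen mitosis;
* type II — lost in one sperm, unchanged in the other (0/1): after the
  second mitosis;
* type III — lost in both sperm (0/0): after the first mitosis.

Cohort tables count pollens with one aneuploid sperm (AP1S), with two
(AP2S), total aneuploid pollens (TP) and aneuploid sperm (ASS/TS), and
compare regular vs inducer lines with a Pearson chi-square (no continuity
correction) on the 2x2 counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .segment import NucleusCall, PloidySegment

__all__ = [
    "TypedEvent",
    "PollenCall",
    "classify_cnv_types",
    "assign_roles",
    "build_pollen_call",
    "summarize_cohort",
    "chisq_2x2",
    "TYPE_TO_STAGE",
]

#: Inferred initiation stage per CNV type (reported as an annotation).
TYPE_TO_STAGE = {
    "I": "around 2nd mitosis",
    "II": "after 2nd mitosis",
    "III": "after 1st mitosis",
}

DEFAULT_RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class TypedEvent:
    chrom: str
    start: int
    end: int
    state1: int
    state2: int
    cnv_type: str | None  # I / II / III, or None for untyped joint states

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class PollenCall:
    pollen_id: str
    nucleus_calls: list[NucleusCall]
    typed_events: list[TypedEvent]
    category: str  # euploid / one_aneuploid_sperm / two_aneuploid_sperm


def _joint_type(a: int, b: int, baseline: int) -> str | None:
    lo, hi = sorted((a, b))
    if baseline == 1:
        if (lo, hi) == (0, 2):
            return "I"
        if (lo, hi) == (0, 1):
            return "II"
        if (lo, hi) == (0, 0):
            return "III"
    return None


def _reciprocal_overlap(a: PloidySegment, b: PloidySegment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.span, inter / b.span)


def _state_at(call: NucleusCall, chrom: str, pos: int) -> int:
    for seg in call.segments:
        if seg.chrom == chrom and seg.start <= pos < seg.end:
            return seg.copy_state
    return call.baseline


def classify_cnv_types(
    sperm1: NucleusCall,
    sperm2: NucleusCall,
    reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> list[TypedEvent]:
    """Type the CNV events of a sperm pair.

    Events from the two segmentations are paired greedily by best
    reciprocal overlap (requiring at least ``reciprocal_overlap``); a
    paired event is typed on the intersection interval from the two copy
    states.  An unpaired event is typed against the partner's copy state
    at the event midpoint.  Both calls must come from the same bin scheme.
    """
    if sperm1.baseline != sperm2.baseline:
        raise ValueError("sperm calls have different baselines")
    if (sperm1.scheme is not None and sperm2.scheme is not None
            and sperm1.scheme is not sperm2.scheme):
        raise ValueError("sperm calls use different bin schemes")
    baseline = sperm1.baseline
    ev1 = list(sperm1.events)
    ev2 = list(sperm2.events)
    pairs: list[tuple[PloidySegment, PloidySegment]] = []
    used2: set[int] = set()
    for e1 in ev1:
        best, best_ov = None, reciprocal_overlap
        for j, e2 in enumerate(ev2):
            if j in used2:
                continue
            ov = _reciprocal_overlap(e1, e2)
            if ov >= best_ov:
                best, best_ov = j, ov
        if best is not None:
            used2.add(best)
            pairs.append((e1, ev2[best]))
    paired1 = {id(a) for a, _ in pairs}
    events: list[TypedEvent] = []
    for a, b in pairs:
        start = max(a.start, b.start)
        end = min(a.end, b.end)
        events.append(TypedEvent(a.chrom, start, end, a.copy_state,
                                 b.copy_state,
                                 _joint_type(a.copy_state, b.copy_state,
                                             baseline)))
    for e in ev1:
        if id(e) not in paired1:
            other = _state_at(sperm2, e.chrom, (e.start + e.end) // 2)
            events.append(TypedEvent(e.chrom, e.start, e.end, e.copy_state,
                                     other,
                                     _joint_type(e.copy_state, other, baseline)))
    for j, e in enumerate(ev2):
        if j not in used2:
            other = _state_at(sperm1, e.chrom, (e.start + e.end) // 2)
            events.append(TypedEvent(e.chrom, e.start, e.end, other,
                                     e.copy_state,
                                     _joint_type(other, e.copy_state, baseline)))
    events.sort(key=lambda e: (e.chrom, e.start))
    return events


def assign_roles(
    calls: list[NucleusCall],
    reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> tuple[list[str], str]:
    """Assign trophic/sperm roles to the three nuclei of one pollen.

    If two nuclei carry a complementary loss/gain pair (copy 0 in one,
    copy 2 in the other on overlapping intervals) they must be the two
    sperm and the remaining nucleus is the trophic one ("complementarity"
    provenance).  Otherwise the sample-sheet roles are retained; the
    provenance is "sheet", or "sheet_unconfirmed" when aneuploidy is
    present but no complementary pair confirms the roles.
    """
    if len(calls) != 3:
        raise ValueError(f"expected 3 nucleus calls, got {len(calls)}")
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            losses = [e for e in calls[i].events if e.copy_state == 0]
            gains = [e for e in calls[j].events if e.copy_state == 2]
            for lo in losses:
                for hi in gains:
                    if _reciprocal_overlap(lo, hi) >= reciprocal_overlap:
                        roles = ["trophic"] * 3
                        roles[i] = roles[j] = "sperm"
                        return roles, "complementarity"
    roles = [c.role for c in calls]
    if any(c.aneuploid for c in calls):
        return roles, "sheet_unconfirmed"
    return roles, "sheet"


def build_pollen_call(
    pollen_id: str,
    calls: list[NucleusCall],
    reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> PollenCall:
    """Joint call for one pollen from its 2 or 3 nucleus calls."""
    if len(calls) == 3:
        roles, _prov = assign_roles(calls, reciprocal_overlap)
        sperm = [c for c, r in zip(calls, roles) if r == "sperm"]
    elif len(calls) == 2:
        sperm = calls
    else:
        raise ValueError(f"pollen {pollen_id!r}: expected 2 or 3 nuclei, "
                         f"got {len(calls)}")
    if len(sperm) != 2:
        raise ValueError(f"pollen {pollen_id!r}: could not identify 2 sperm")
    typed = classify_cnv_types(sperm[0], sperm[1], reciprocal_overlap)
    n_aneuploid = sum(c.aneuploid for c in sperm)
    category = {0: "euploid", 1: "one_aneuploid_sperm",
                2: "two_aneuploid_sperm"}[n_aneuploid]
    return PollenCall(pollen_id, calls, typed, category)


def summarize_cohort(
    pollen_calls: list[PollenCall],
    lines: pd.DataFrame,
) -> pd.DataFrame:
    """Cohort frequency table: AP1S/AP2S/TP/ASS per line plus pooled rows.

    ``lines`` maps pollen_id to line and group ("regular"/"inducer"):
    columns pollen_id, line, group.  Counts are returned as numerator/
    denominator pairs; TP = AP1S + AP2S over pollens, ASS over sperm.
    The result is invariant to sample order.
    """
    meta = lines.set_index("pollen_id")
    rows = []
    by_line: dict[str, list[PollenCall]] = {}
    for pc in pollen_calls:
        by_line.setdefault(meta.loc[pc.pollen_id, "line"], []).append(pc)

    def _count(calls: list[PollenCall]) -> dict:
        n = len(calls)
        ap1 = sum(pc.category == "one_aneuploid_sperm" for pc in calls)
        ap2 = sum(pc.category == "two_aneuploid_sperm" for pc in calls)
        n_sperm = 2 * n
        aneu_sperm = ap1 + 2 * ap2
        return {"ap1s_n": ap1, "ap2s_n": ap2, "tp_n": ap1 + ap2,
                "pollens": n, "ass_n": aneu_sperm, "sperms": n_sperm}

    for line in sorted(by_line):
        group = meta.loc[meta["line"] == line, "group"].iloc[0]
        rows.append({"line": line, "group": group, **_count(by_line[line])})
    for group in ("regular", "inducer"):
        calls = [pc for pc in pollen_calls
                 if meta.loc[pc.pollen_id, "group"] == group]
        if calls:
            rows.append({"line": f"pooled_{group}", "group": group,
                         **_count(calls)})
    return pd.DataFrame(rows)


def chisq_2x2(table) -> tuple[float, float, int]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (statistic, two-sided p-value, df=1).  The statistic is
    sum((O - E)^2 / E) with E the usual product-of-margins expectation;
    this is the only variant that reproduces the published P values from
    the printed cohort counts.  Degenerate tables (a zero margin) raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, 1))
    return stat, p, 1
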