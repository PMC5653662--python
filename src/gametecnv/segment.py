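"""Integer copy-state segmentation of log2(CNR) profiles.

The calling rule operationalizes visible-step ploidy calling: each bin is
assigned the copy state whose expected log2(CNR) it is closest to, runs of
equal-state bins become candidate segments, and candidates that are short
(below a minimum span, 10 Mb at full genome scale) or whose mean log2(CNR)
sits inside a no-call band around the baseline are absorbed into their
flanks.  No HMM or changepoint machinery is used, which keeps the
noiseless oracle exact: on clean profiles the recovered segments equal the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bins import CNRProfile
from .sim import GenomeLayout

__all__ = [
    "PloidySegment",
    "NucleusCall",
    "segment_profile",
    "call_nucleus",
    "scaled_min_seg_bp",
    "DEFAULT_MIN_SEG_BP",
    "DEFAULT_NO_CALL_BAND",
    "REFERENCE_GENOME_BP",
]

#: Minimum segment span on the full-scale (~2 Gb) genome.
DEFAULT_MIN_SEG_BP = 10_000_000
#: Reference genome size used to scale bp thresholds for small test genomes.
REFERENCE_GENOME_BP = 2_000_000_000
#: Half-width of the no-call band around the baseline, in log2 units.
DEFAULT_NO_CALL_BAND = 0.35


def scaled_min_seg_bp(
    genome: GenomeLayout,
    base_bp: int = DEFAULT_MIN_SEG_BP,
    reference_bp: int = REFERENCE_GENOME_BP,
) -> int:
    """Scale the 10 Mb minimum-segment rule by genome-size ratio."""
    return max(1, int(round(base_bp * genome.total_bp / reference_bp)))


@dataclass(frozen=True)
class PloidySegment:
    chrom: str
    start: int
    end: int
    copy_state: int
    mean_log2: float
    n_bins: int
    centromere_overlap: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class NucleusCall:
    """Segmentation result for one nucleus/sample."""

    sample_id: str
    role: str
    baseline: int
    segments: list[PloidySegment]
    aneuploid: bool
    affected_fraction: float
    events: list[PloidySegment] = field(default_factory=list)
    scheme: object | None = None


def _expected_log2(state: int, baseline: int, floor: float) -> float:
    if state == 0:
        return floor
    return float(np.log2(state / baseline))


def segment_profile(
    profile: CNRProfile,
    baseline: int,
    min_seg_bp: int,
    state_set: tuple[int, ...] = (0, 1, 2),
    no_call_band: float = DEFAULT_NO_CALL_BAND,
    genome: GenomeLayout | None = None,
) -> list[PloidySegment]:
    """Segment a log2(CNR) profile into integer copy states.

    Steps: (1) assign each unmasked bin the state in ``state_set`` whose
    expected log2(CNR) — log2(state/baseline), with copy 0 mapped to the
    zero-count pseudocount floor — is nearest (ties toward baseline);
    (2) runs of equal-state bins become candidate segments; (3) non-
    baseline candidates whose mean log2(CNR) lies within ``no_call_band``
    of 0 are demoted to baseline, and candidates spanning less than
    ``min_seg_bp`` are absorbed into the common flanking state when both
    flanks agree, otherwise into baseline; (4) adjacent same-state
    segments merge.  Masked bins carry no state and are spanned by
    whichever segment surrounds them.
    """
    if baseline not in state_set:
        raise ValueError(f"baseline {baseline} not in state_set {state_set}")
    scheme = profile.scheme
    genome = genome or scheme.genome
    floor = profile.zero_floor_log2
    states = np.asarray(sorted(state_set))
    expected = np.array([_expected_log2(s, baseline, floor) for s in states])

    bin_chrom = scheme.bins["chrom"].to_numpy()
    bin_start = scheme.bins["start"].to_numpy()
    bin_end = scheme.bins["end"].to_numpy()
    segments: list[PloidySegment] = []
    for chrom in genome.names:
        sel = np.nonzero((bin_chrom == chrom) & ~profile.masked)[0]
        if sel.size == 0:
            continue
        vals = profile.log2_cnr[sel]
        dist = np.abs(vals[:, None] - expected[None, :])
        # tie-break toward baseline: shave an epsilon off its distance
        dist[:, np.nonzero(states == baseline)[0][0]] -= 1e-12
        assigned = states[np.argmin(dist, axis=1)]

        # runs of equal state -> candidates as (state, first_idx, last_idx)
        runs: list[list[int]] = []
        for k, st in enumerate(assigned):
            if runs and runs[-1][0] == st:
                runs[-1][2] = k
            else:
                runs.append([int(st), k, k])

        def run_span(r):
            return int(bin_end[sel[r[2]]] - bin_start[sel[r[1]]])

        def run_mean(r):
            return float(np.mean(vals[r[1]: r[2] + 1]))

        changed = True
        guard = 0
        while changed and len(runs) > 1 and guard < 4 * len(assigned):
            guard += 1
            changed = False
            # demote in-band non-baseline runs
            for r in runs:
                if r[0] != baseline and abs(run_mean(r)) <= no_call_band:
                    r[0] = baseline
                    changed = True
            runs = _merge_adjacent(runs)
            if len(runs) <= 1:
                break
            # absorb short runs, shortest first
            order = sorted(range(len(runs)), key=lambda i: run_span(runs[i]))
            for i in order:
                r = runs[i]
                if run_span(r) >= min_seg_bp:
                    continue
                left = runs[i - 1][0] if i > 0 else None
                right = runs[i + 1][0] if i < len(runs) - 1 else None
                if left is not None and left == right:
                    new_state = left
                elif r[0] != baseline:
                    new_state = baseline
                else:
                    continue
                if new_state != r[0]:
                    r[0] = new_state
                    changed = True
                    break  # re-merge before absorbing further
            runs = _merge_adjacent(runs)

        for st, i0, i1 in runs:
            idx = sel[i0: i1 + 1]
            start = int(bin_start[idx[0]])
            end = int(bin_end[idx[-1]])
            overlap = False
            if chrom in genome.centromeres:
                cs, ce = genome.centromeres[chrom]
                overlap = start < ce and cs < end
            segments.append(PloidySegment(
                chrom, start, end, int(st),
                float(np.mean(profile.log2_cnr[idx])), len(idx), overlap))
    return segments


def _merge_adjacent(runs: list[list[int]]) -> list[list[int]]:
    merged: list[list[int]] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    return merged


def call_nucleus(
    segments: list[PloidySegment],
    genome: GenomeLayout,
    baseline: int,
    sample_id: str = ".",
    role: str = "sperm",
    scheme=None,
) -> NucleusCall:
    """Summarize segments into a per-nucleus aneuploidy call.

    A nucleus is aneuploid iff at least one segment deviates from the
    baseline copy state (segments below the minimum span were already
    absorbed during segmentation).  The affected fraction is non-baseline
    bp over total segmented bp; each event keeps its centromere-overlap
    flag.
    """
    events = [s for s in segments if s.copy_state != baseline]
    total = sum(s.span for s in segments)
    affected = sum(s.span for s in events)
    return NucleusCall(
        sample_id=sample_id,
        role=role,
        baseline=baseline,
        segments=list(segments),
        aneuploid=bool(events),
        affected_fraction=affected / total if total else 0.0,
        events=events,
        scheme=scheme,
    )
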