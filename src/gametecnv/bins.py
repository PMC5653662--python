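"""Uniform-depth variable binning and per-sample CNR profiles.

Whole-genome-amplified single-nucleus libraries have strong locus-specific
coverage bias shared across samples.  The remedy implemented here is the
two-stage scheme: (1) split the genome into fixed, equal-width bins to set
a target pooled depth; (2) re-partition each chromosome into variable-
length bins that each hold the same number of *pooled* reads across all
samples, so per-sample counts per bin are comparable.  Per sample, the
copy-number ratio CNR of a bin is its read count divided by the sample's
median bin count (so euploid bins sit near 1, and near 0 after log2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import GenomeLayout

logger = logging.getLogger("gametecnv")

__all__ = [
    "BinScheme",
    "CNRProfile",
    "init_fixed_bins",
    "pooled_counts",
    "redefine_uniform_depth_bins",
    "cnr_profile",
    "filter_mapq",
]

DEFAULT_MAPQ_MIN = 10
DEFAULT_PSEUDOCOUNT = 0.5


def filter_mapq(placements: pd.DataFrame, mapq_min: int = DEFAULT_MAPQ_MIN):
    """Keep reads with MapQ >= ``mapq_min`` (inclusive, idempotent)."""
    return placements[placements["mapq"] >= mapq_min]


@dataclass
class BinScheme:
    """An ordered genome partition into bins.

    ``stage`` is "fixed" (equal widths) or "variable" (uniform pooled
    depth).  For variable schemes, ``pooled_counts`` records the pooled
    per-bin read counts used to draw the boundaries, and bins with zero
    pooled reads are masked (excluded from medians and segmentation).
    """

    bins: pd.DataFrame  # columns chrom, start, end
    stage: str
    genome: GenomeLayout
    target_depth: int | None = None
    pooled_counts: np.ndarray | None = None
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = np.zeros(len(self.bins), dtype=bool)
        self.validate_partition()

    def __len__(self) -> int:
        return len(self.bins)

    def validate_partition(self) -> None:
        """Assert bins tile each chromosome exactly: no gap, no overlap."""
        seen = set()
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            seen.add(chrom)
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.genome.length(chrom):
                raise ValueError(f"bins do not span chromosome {chrom!r}")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"bins on {chrom!r} have gaps or overlaps")
        missing = set(self.genome.names) - seen
        if missing:
            raise ValueError(f"chromosomes without bins: {sorted(missing)}")

    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def _largest_remainder(lengths: np.ndarray, n_bins: int) -> np.ndarray:
    """Allocate n_bins to chromosomes ∝ length; leftmost wins remainder
    ties; every chromosome gets at least one bin."""
    quota = n_bins * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    frac = quota - alloc
    # stable sort on -frac => leftmost wins ties
    order = np.argsort(-frac, kind="stable")
    for i in order[: n_bins - alloc.sum()]:
        alloc[i] += 1
    while (alloc == 0).any():
        alloc[np.argmax(alloc == 0)] += 1
        alloc[np.argmax(alloc)] -= 1
    return alloc


def init_fixed_bins(genome: GenomeLayout, n_bins: int = 4000) -> BinScheme:
    """Equal-width bins, allocated to chromosomes by largest remainder.

    Within a chromosome bin widths differ by at most 1 bp (the remainder
    bp are spread over the leading bins).
    """
    if n_bins < len(genome.chromosomes):
        raise ValueError("n_bins must be at least the number of chromosomes")
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    alloc = _largest_remainder(lengths, n_bins)
    rows = []
    for (chrom, length), k in zip(genome.chromosomes, alloc):
        base, rem = divmod(length, int(k))
        widths = np.full(int(k), base, dtype=np.int64)
        widths[:rem] += 1
        ends = np.cumsum(widths)
        starts = ends - widths
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return BinScheme(pd.concat(rows, ignore_index=True), "fixed", genome)


def pooled_counts(
    placements: pd.DataFrame,
    scheme: BinScheme,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> np.ndarray:
    """Per-bin read counts; a read belongs to the bin containing its start.

    Counts sum to the number of MapQ-kept reads; reads on chromosomes not
    in the scheme's genome are an error.
    """
    kept = filter_mapq(placements, mapq_min)
    counts = np.zeros(len(scheme), dtype=np.int64)
    bin_chrom = scheme.bins["chrom"].to_numpy()
    unknown = set(kept["chrom"].unique()) - set(scheme.genome.names)
    if unknown:
        raise ValueError(f"reads on unknown chromosome(s) {sorted(unknown)}")
    for chrom, sub in kept.groupby("chrom", sort=False):
        sel = np.nonzero(bin_chrom == chrom)[0]
        starts = scheme.bins["start"].to_numpy()[sel]
        idx = np.searchsorted(starts, sub["start"].to_numpy(), side="right") - 1
        counts[sel[0]:sel[0] + len(sel)] += np.bincount(idx, minlength=len(sel))
    return counts


def redefine_uniform_depth_bins(
    genome: GenomeLayout,
    pooled: pd.DataFrame,
    target_depth: int,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> BinScheme:
    """Variable-length bins holding ~``target_depth`` pooled reads each.

    Walks each chromosome left to right accumulating pooled reads and
    closes a bin at the end coordinate of the read that brings the running
    count to ``target_depth``; reads starting before that coordinate still
    belong to the closed bin, so pooled counts lie in
    [target, target + per-position multiplicity) except for the last bin
    of each chromosome, into which the trailing partial remainder is
    merged.  Chromosomes with zero pooled reads become a single
    whole-chromosome masked bin (with a warning).
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    kept = filter_mapq(pooled, mapq_min)
    if len(kept) < target_depth:
        raise ValueError("total pooled reads below target_depth")
    rows = []
    pooled_per_bin: list[int] = []
    masked: list[bool] = []
    for chrom, length in genome.chromosomes:
        sub = kept[kept["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends = sub["end"].to_numpy()[order]
        n = len(starts)
        if n == 0:
            logger.warning("no pooled reads on %s: whole-chromosome masked bin",
                           chrom)
            rows.append((chrom, 0, length))
            pooled_per_bin.append(0)
            masked.append(True)
            continue
        boundaries: list[int] = []  # ends of completed bins
        bin_counts: list[int] = []
        i = 0
        prev = 0
        while n - i >= target_depth:
            j = i + target_depth - 1
            e = int(ends[j])
            # reads starting before e also fall in this bin
            j2 = int(np.searchsorted(starts, e, side="left")) - 1
            j = max(j, j2)
            e = max(e, prev + 1)  # keep boundaries strictly increasing
            boundaries.append(min(e, length))
            bin_counts.append(j + 1 - i)
            i = j + 1
            prev = boundaries[-1]
            if prev >= length:
                break
        leftover = n - i
        if not boundaries:
            rows.append((chrom, 0, length))
            pooled_per_bin.append(n)
            masked.append(n == 0)
            continue
        # last complete bin absorbs the trailing remainder: its closing
        # boundary is replaced by the chromosome end.
        internal = boundaries[:-1]
        edges = [0, *internal, length]
        for k in range(len(edges) - 1):
            rows.append((chrom, edges[k], edges[k + 1]))
        counts = bin_counts[:-1] + [bin_counts[-1] + leftover]
        pooled_per_bin.extend(counts)
        masked.extend(c == 0 for c in counts)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BinScheme(
        bins, "variable", genome, target_depth=int(target_depth),
        pooled_counts=np.asarray(pooled_per_bin, dtype=np.int64),
        masked=np.asarray(masked, dtype=bool),
    )


@dataclass
class CNRProfile:
    """Per-sample copy-number-ratio profile over a bin scheme.

    CNR_b = count_b / median(count over unmasked bins); log2(CNR) replaces
    exact zero counts by ``pseudocount`` reads before the division so the
    log stays finite.  The median of unmasked CNR values is exactly 1.

    For variable schemes the raw count is first divided by the bin's
    pooled-depth share (pooled count / target depth).  Every regular bin
    holds almost exactly the target pooled depth, so the correction is a
    no-op there; it matters only for the merged trailing bin of each
    chromosome, which holds up to twice the target and would otherwise
    masquerade as a copy gain in every sample.
    """

    sample_id: str
    scheme: BinScheme
    counts: np.ndarray
    cnr: np.ndarray
    log2_cnr: np.ndarray
    masked: np.ndarray
    median_count: float
    pseudocount: float

    @property
    def zero_floor_log2(self) -> float:
        """log2 value assigned to a zero-count bin (the copy-0 floor)."""
        return float(np.log2(self.pseudocount / self.median_count))


def cnr_profile(
    placements: pd.DataFrame,
    scheme: BinScheme,
    sample_id: str = ".",
    mapq_min: int = DEFAULT_MAPQ_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CNRProfile:
    """Compute a sample's CNR and log2(CNR) profile on a bin scheme."""
    counts = pooled_counts(placements, scheme, mapq_min)
    masked = scheme.masked.copy()
    eff = counts.astype(float)
    if scheme.pooled_counts is not None and scheme.target_depth:
        # depth-share correction (exact for the merged trailing bins)
        share = scheme.pooled_counts / scheme.target_depth
        eff = np.divide(counts, share, out=np.zeros_like(eff),
                        where=share > 0)
    unmasked = eff[~masked]
    if len(unmasked) == 0 or unmasked.sum() == 0:
        raise ValueError(f"sample {sample_id!r}: no usable coverage")
    median = float(np.median(unmasked))
    if median == 0:
        raise ValueError(f"sample {sample_id!r}: median bin count is zero")
    cnr = eff / median
    adjusted = np.where(counts == 0, pseudocount, eff)
    log2 = np.log2(adjusted / median)
    return CNRProfile(sample_id, scheme, counts, cnr, log2, masked,
                      median, pseudocount)
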