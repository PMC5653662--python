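"""Parental-origin analysis of hybrid embryo and endosperm samples.

At low sequencing depth, per-SNP genotypes are unreliable, so parent-
informative SNPs are pooled into bins of k adjacent SNPs (default 700)
and the maternal-allele read fraction (SNP ratio) is computed per bin.
In a euploid hybrid the ratio sits near 0.5 in the diploid embryo
(1 maternal : 1 paternal genome) and near 2/3 in the triploid endosperm
(2:1).  To cancel locus-specific artifacts the relative genotype ratio
RGR — a sample's bin ratio divided by the cross-sample mean for that bin,
log2-transformed — is used: log2(RGR) > 0 indicates paternal genome loss,
< 0 maternal loss.

Kernel classes combine RGR with copy-number segmentation (baseline 2 for
embryo, 3 for endosperm): class I is genome-wide elimination of one
parental genome (complete, or incomplete with retained fragments);
class II is a local fragment loss from either parent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .segment import NucleusCall
from .sim import GenomeLayout

__all__ = [
    "SNPBinScheme",
    "SNPRatioTrack",
    "RGRProfile",
    "KernelCall",
    "RGRThresholds",
    "default_thresholds",
    "build_snp_bins",
    "snp_ratio",
    "rgr_profile",
    "classify_kernel",
    "cohort_kernel_report",
]

DEFAULT_SNPS_PER_BIN = 700
DEFAULT_MIN_READS = 50
DEFAULT_GENOME_WIDE_FRACTION = 0.95
DEFAULT_PARTIAL_FRACTION = 0.5


@dataclass
class SNPBinScheme:
    """Runs of k adjacent panel SNPs, with their genomic spans.

    Bins partition the panel in order; only the final bin of each
    chromosome may hold fewer than k SNPs.  A bin's span runs from its
    first SNP position to its last SNP position + 1 (half-open).
    """

    bins: pd.DataFrame  # chrom, start, end, n_snps, first_idx, last_idx
    k: int
    panel: pd.DataFrame

    def __len__(self) -> int:
        return len(self.bins)

    def spans(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def build_snp_bins(panel: pd.DataFrame, k: int = DEFAULT_SNPS_PER_BIN) -> SNPBinScheme:
    """Group consecutive runs of ``k`` panel SNPs per chromosome."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    rows = []
    for chrom, sub in panel.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        for i0 in range(0, len(idx), k):
            i1 = min(i0 + k, len(idx)) - 1
            rows.append((chrom, int(pos[i0]), int(pos[i1]) + 1,
                         i1 - i0 + 1, int(idx[i0]), int(idx[i1])))
    bins = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_snps", "first_idx", "last_idx"])
    return SNPBinScheme(bins, k, panel)


@dataclass
class SNPRatioTrack:
    """Per-bin maternal-allele read fractions for one sample."""

    sample_id: str
    ratio: np.ndarray        # in [0, 1]; NaN where masked
    informative: np.ndarray  # maternal + paternal reads per bin
    masked: np.ndarray       # informative < min_reads
    scheme: SNPBinScheme


def snp_ratio(
    counts: pd.DataFrame,
    scheme: SNPBinScheme,
    min_reads: int = DEFAULT_MIN_READS,
    sample_id: str = ".",
) -> SNPRatioTrack:
    """Pool allele counts per SNP bin into maternal-allele fractions.

    ``counts`` must cover panel SNPs (chrom, pos, maternal_count,
    paternal_count); bins with fewer than ``min_reads`` informative reads
    are masked.
    """
    panel = scheme.panel
    merged = panel[["chrom", "pos"]].merge(
        counts, on=["chrom", "pos"], how="left", validate="one_to_one")
    m = merged["maternal_count"].fillna(0).to_numpy(dtype=float)
    f = merged["paternal_count"].fillna(0).to_numpy(dtype=float)
    offsets = scheme.bins["first_idx"].to_numpy()
    mat = np.add.reduceat(m, offsets)
    tot = mat + np.add.reduceat(f, offsets)
    masked = tot < min_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, mat / np.maximum(tot, 1), np.nan)
    ratio = np.where(masked, np.nan, ratio)
    return SNPRatioTrack(sample_id, ratio, tot, masked, scheme)


@dataclass
class RGRProfile:
    """Cross-sample-normalized log2 relative genotype ratio per bin."""

    sample_id: str
    ratio: np.ndarray
    mean_ratio: np.ndarray  # cross-sample per-bin mean (shared)
    log2_rgr: np.ndarray
    informative: np.ndarray
    masked: np.ndarray
    scheme: SNPBinScheme


def rgr_profile(tracks: Mapping[str, SNPRatioTrack]) -> dict[str, RGRProfile]:
    """Normalize each sample's SNP ratios by the per-bin cross-sample mean.

    The mean excludes masked entries; a bin masked in every sample stays
    masked in every output.  log2 is kept finite by flooring a zero ratio
    at the value half a read would give (0.5 / informative reads).
    """
    if len(tracks) < 2:
        raise ValueError("RGR normalization needs at least 2 samples")
    ids = list(tracks)
    scheme = tracks[ids[0]].scheme
    ratios = np.vstack([tracks[s].ratio for s in ids])
    masked = np.vstack([tracks[s].masked for s in ids])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-masked bins
        mean = np.nanmean(np.where(masked, np.nan, ratios), axis=0)
    all_masked = masked.all(axis=0)
    out: dict[str, RGRProfile] = {}
    for i, s in enumerate(ids):
        tr = tracks[s]
        bin_mask = tr.masked | all_masked | ~np.isfinite(mean) | (mean <= 0)
        floor = 0.5 / np.maximum(tr.informative, 1)
        adj = np.maximum(tr.ratio, floor)
        with np.errstate(invalid="ignore", divide="ignore"):
            log2 = np.log2(adj / mean)
        log2 = np.where(bin_mask, np.nan, log2)
        out[s] = RGRProfile(s, tr.ratio, mean, log2, tr.informative,
                            bin_mask, scheme)
    return out


@dataclass(frozen=True)
class RGRThresholds:
    """log2(RGR) thresholds flagging parental loss, per tissue.

    The embryo values mark half the shift a full loss produces
    (ratio 0.5 -> 1 is +1 in log2; 0.5 -> 0 is unbounded below).  For the
    triploid endosperm the dosage arithmetic gives smaller shifts — losing
    the single paternal copy moves the ratio 2/3 -> 1 (log2 +0.585);
    losing one maternal copy moves it 2/3 -> 1/2 (log2 -0.415) — so the
    thresholds sit at half of those.
    """

    paternal_loss: float  # flag paternal loss where log2(RGR) > this
    maternal_loss: float  # flag maternal loss where log2(RGR) < this


def default_thresholds(tissue: str) -> RGRThresholds:
    if tissue == "embryo":
        return RGRThresholds(0.3, -0.3)
    if tissue == "endosperm":
        return RGRThresholds(0.29, -0.21)
    raise ValueError(f"unknown tissue {tissue!r}")


@dataclass
class KernelCall:
    kernel_id: str
    tissue: str
    cls: str  # euploid / classI_complete / classI_incomplete /
    #           classII_paternal / classII_maternal
    eliminated_parent: str | None = None
    retained_fragments: list[tuple[str, int, int]] = field(default_factory=list)
    supporting_segments: list = field(default_factory=list)
    unconfirmed_segments: list = field(default_factory=list)


def _contiguous_bins(idx: np.ndarray) -> list[np.ndarray]:
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) != 1)[0]
    return np.split(idx, breaks + 1)


def classify_kernel(
    cnv: NucleusCall,
    rgr: RGRProfile,
    genome: GenomeLayout,
    tissue: str,
    min_seg_bp: int,
    thresholds: RGRThresholds | None = None,
    genome_wide_fraction: float = DEFAULT_GENOME_WIDE_FRACTION,
    partial_fraction: float = DEFAULT_PARTIAL_FRACTION,
    kernel_id: str = ".",
) -> KernelCall:
    """Combine copy-number segments and RGR into a kernel class.

    Decision rule, with fractions measured over unmasked SNP-bin bp:
    (a) parental-loss fraction >= ``genome_wide_fraction`` and a CNV
    profile consistent with a uniform genome-wide one-copy drop -> class I
    complete.  Median-normalized relative depth cannot detect a drop that
    affects the whole genome (the profile renormalizes to flat — the very
    reason the SNP ratio is needed), so consistency means a single copy
    state covering at least ``genome_wide_fraction`` of the segmented
    genome.  (b) parental-loss fraction >= ``partial_fraction``
    with contiguous not-lost gaps of at least ``min_seg_bp`` -> class I
    incomplete, the gaps being the retained fragments; (c) otherwise any
    CNV loss segment of at least ``min_seg_bp`` whose mean log2(RGR)
    crosses a loss threshold -> class II with the parent given by the RGR
    sign; CNV segments without RGR support are reported as unconfirmed,
    not classified; (d) otherwise euploid.
    """
    if cnv.baseline != {"embryo": 2, "endosperm": 3}[tissue]:
        raise ValueError(
            f"tissue {tissue!r} expects baseline "
            f"{ {'embryo': 2, 'endosperm': 3}[tissue] }, got {cnv.baseline}")
    thr = thresholds or default_thresholds(tissue)
    bins = rgr.scheme.bins
    spans = rgr.scheme.spans().astype(float)
    ok = ~rgr.masked
    total_bp = spans[ok].sum()
    if total_bp == 0:
        raise ValueError(f"kernel {kernel_id!r}: all SNP bins masked")

    pat_lost = ok & (rgr.log2_rgr > thr.paternal_loss)
    mat_lost = ok & (rgr.log2_rgr < thr.maternal_loss)
    pat_frac = spans[pat_lost].sum() / total_bp
    mat_frac = spans[mat_lost].sum() / total_bp

    seg_total = sum(s.span for s in cnv.segments)
    state_bp: dict[int, int] = {}
    for s in cnv.segments:
        state_bp[s.copy_state] = state_bp.get(s.copy_state, 0) + s.span
    cnv_flat_frac = (max(state_bp.values()) / seg_total) if seg_total else 0.0

    for parent, frac, lost in (("paternal", pat_frac, pat_lost),
                               ("maternal", mat_frac, mat_lost)):
        if frac >= genome_wide_fraction and cnv_flat_frac >= genome_wide_fraction:
            return KernelCall(kernel_id, tissue, "classI_complete", parent)
        if frac >= partial_fraction:
            retained: list[tuple[str, int, int]] = []
            for chrom in genome.names:
                on_chrom = (bins["chrom"] == chrom).to_numpy() & ok
                gap_idx = np.nonzero(on_chrom & ~lost)[0]
                for run in _contiguous_bins(gap_idx):
                    start = int(bins["start"].iloc[run[0]])
                    end = int(bins["end"].iloc[run[-1]])
                    if end - start >= min_seg_bp:
                        retained.append((chrom, start, end))
            if retained:
                return KernelCall(kernel_id, tissue, "classI_incomplete",
                                  parent, retained_fragments=retained)

    supporting, unconfirmed = [], []
    parent_votes: list[str] = []
    bin_chrom = bins["chrom"].to_numpy()
    bin_start = bins["start"].to_numpy()
    bin_end = bins["end"].to_numpy()
    for seg in cnv.events:
        if seg.span < min_seg_bp or seg.copy_state >= cnv.baseline:
            continue
        overlap = (ok & (bin_chrom == seg.chrom)
                   & (bin_start < seg.end) & (bin_end > seg.start))
        if not overlap.any():
            unconfirmed.append(seg)
            continue
        mean_rgr = float(np.nanmean(rgr.log2_rgr[overlap]))
        if mean_rgr > thr.paternal_loss:
            supporting.append(seg)
            parent_votes.append("paternal")
        elif mean_rgr < thr.maternal_loss:
            supporting.append(seg)
            parent_votes.append("maternal")
        else:
            unconfirmed.append(seg)
    if supporting:
        # parent of the largest supported loss decides the label
        order = np.argsort([-s.span for s in supporting])
        parent = parent_votes[int(order[0])]
        return KernelCall(kernel_id, tissue, f"classII_{parent}", parent,
                          supporting_segments=supporting,
                          unconfirmed_segments=unconfirmed)
    return KernelCall(kernel_id, tissue, "euploid",
                      unconfirmed_segments=unconfirmed)


def cohort_kernel_report(calls: list[KernelCall]) -> pd.DataFrame:
    """Counts per class per tissue, as numerator/denominator plus fraction."""
    rows = []
    classes = ["euploid", "classI_complete", "classI_incomplete",
               "classII_paternal", "classII_maternal"]
    for tissue in ("embryo", "endosperm"):
        sub = [c for c in calls if c.tissue == tissue]
        if not sub:
            continue
        for cls in classes:
            n = sum(c.cls == cls for c in sub)
            rows.append({"tissue": tissue, "class": cls, "count": n,
                         "total": len(sub), "fraction": n / len(sub)})
    return pd.DataFrame(rows)
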