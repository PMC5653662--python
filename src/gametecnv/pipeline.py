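"""End-to-end drivers: placements -> bins -> CNR -> segments -> calls.

These functions wire the per-module operations together the way the CLI
and the recovery tests use them; all thresholds stay overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import bins as cb
from . import gametes as gm
from . import kernels as kn
from . import segment as sg
from .sim import GenomeLayout

__all__ = [
    "PollenPipelineResult",
    "run_pollen_pipeline",
    "KernelPipelineResult",
    "run_kernel_pipeline",
]


@dataclass
class PollenPipelineResult:
    schemes: dict[str, cb.BinScheme]        # per line
    profiles: dict[str, cb.CNRProfile]      # per sample
    calls: dict[str, sg.NucleusCall]        # per sample
    pollen_calls: list[gm.PollenCall]
    summary: pd.DataFrame


def run_pollen_pipeline(
    genome: GenomeLayout,
    samples: pd.DataFrame,
    placements: dict[str, pd.DataFrame],
    n_fixed_bins: int = 800,
    mapq_min: int = cb.DEFAULT_MAPQ_MIN,
    min_seg_bp: int | None = None,
    state_set: tuple[int, ...] = (0, 1, 2),
    no_call_band: float = sg.DEFAULT_NO_CALL_BAND,
) -> PollenPipelineResult:
    """Full single-nucleus CNV pipeline over a pollen/tetrad cohort.

    Samples are pooled per line to draw the uniform-depth variable bins
    (target depth = pooled reads / ``n_fixed_bins``, the per-line pooled
    average depth of the fixed scheme); each nucleus is then profiled,
    segmented at haploid baseline and joined per pollen into CNV types
    and the cohort frequency table.
    """
    if min_seg_bp is None:
        min_seg_bp = sg.scaled_min_seg_bp(genome)
    schemes: dict[str, cb.BinScheme] = {}
    profiles: dict[str, cb.CNRProfile] = {}
    calls: dict[str, sg.NucleusCall] = {}
    for line, sub in samples.groupby("line", sort=False):
        ids = sub["sample_id"].tolist()
        pooled = pd.concat([placements[s] for s in ids], ignore_index=True)
        kept = cb.filter_mapq(pooled, mapq_min)
        target = max(1, len(kept) // n_fixed_bins)
        scheme = cb.redefine_uniform_depth_bins(genome, kept, target,
                                               mapq_min=mapq_min)
        schemes[line] = scheme
        for row in sub.itertuples():
            prof = cb.cnr_profile(placements[row.sample_id], scheme,
                                  sample_id=row.sample_id, mapq_min=mapq_min)
            profiles[row.sample_id] = prof
            segs = sg.segment_profile(prof, baseline=1, min_seg_bp=min_seg_bp,
                                      state_set=state_set,
                                      no_call_band=no_call_band,
                                      genome=genome)
            calls[row.sample_id] = sg.call_nucleus(
                segs, genome, 1, sample_id=row.sample_id, role=row.role,
                scheme=scheme)

    pollen_calls: list[gm.PollenCall] = []
    line_rows = []
    for unit, sub in samples.groupby("unit_id", sort=False):
        unit_calls = [calls[s] for s in sub["sample_id"]]
        pollen_calls.append(gm.build_pollen_call(unit, unit_calls))
        line_rows.append({"pollen_id": unit, "line": sub["line"].iloc[0],
                          "group": sub["group"].iloc[0]})
    summary = gm.summarize_cohort(pollen_calls, pd.DataFrame(line_rows))
    return PollenPipelineResult(schemes, profiles, calls, pollen_calls, summary)


@dataclass
class KernelPipelineResult:
    schemes: dict[str, cb.BinScheme]          # per tissue
    cnv_calls: dict[str, sg.NucleusCall]      # per sample
    rgr: dict[str, kn.RGRProfile]             # per sample
    kernel_calls: dict[str, kn.KernelCall]    # per sample
    report: pd.DataFrame


#: Copy-state sets searched per tissue (baseline 2 for the diploid embryo,
#: 3 for the triploid endosperm).
TISSUE_BASELINES = {"embryo": (2, (0, 1, 2, 3)),
                    "endosperm": (3, (0, 1, 2, 3, 4))}


def run_kernel_pipeline(
    genome: GenomeLayout,
    samples: pd.DataFrame,
    placements: dict[str, pd.DataFrame],
    allele_counts: dict[str, pd.DataFrame],
    panel: pd.DataFrame,
    n_fixed_bins: int = 800,
    snps_per_bin: int = kn.DEFAULT_SNPS_PER_BIN,
    min_reads: int = kn.DEFAULT_MIN_READS,
    mapq_min: int = cb.DEFAULT_MAPQ_MIN,
    min_seg_bp: int | None = None,
    no_call_band: float = sg.DEFAULT_NO_CALL_BAND,
) -> KernelPipelineResult:
    """Full kernel pipeline: CNV segmentation + SNP-ratio/RGR -> classes.

    Samples are pooled per tissue to draw the variable bins; RGR is
    normalized within each tissue (the cross-sample mean includes the
    aberrant samples, which attenuates the signal slightly — a tolerance
    the thresholds allow for).
    """
    if min_seg_bp is None:
        min_seg_bp = sg.scaled_min_seg_bp(genome)
    snp_scheme = kn.build_snp_bins(panel, k=snps_per_bin)
    schemes: dict[str, cb.BinScheme] = {}
    cnv_calls: dict[str, sg.NucleusCall] = {}
    rgr_all: dict[str, kn.RGRProfile] = {}
    kernel_calls: dict[str, kn.KernelCall] = {}
    for tissue, sub in samples.groupby("role", sort=False):
        baseline, state_set = TISSUE_BASELINES[tissue]
        ids = sub["sample_id"].tolist()
        pooled = pd.concat([placements[s] for s in ids], ignore_index=True)
        kept = cb.filter_mapq(pooled, mapq_min)
        target = max(1, len(kept) // n_fixed_bins)
        scheme = cb.redefine_uniform_depth_bins(genome, kept, target,
                                               mapq_min=mapq_min)
        schemes[tissue] = scheme
        tracks = {}
        for sid in ids:
            prof = cb.cnr_profile(placements[sid], scheme, sample_id=sid,
                                  mapq_min=mapq_min)
            segs = sg.segment_profile(prof, baseline=baseline,
                                      min_seg_bp=min_seg_bp,
                                      state_set=state_set,
                                      no_call_band=no_call_band,
                                      genome=genome)
            cnv_calls[sid] = sg.call_nucleus(segs, genome, baseline,
                                             sample_id=sid, role=tissue,
                                             scheme=scheme)
            tracks[sid] = kn.snp_ratio(allele_counts[sid], snp_scheme,
                                       min_reads=min_reads, sample_id=sid)
        profiles = kn.rgr_profile(tracks)
        rgr_all.update(profiles)
        for sid in ids:
            kernel_calls[sid] = kn.classify_kernel(
                cnv_calls[sid], profiles[sid], genome, tissue,
                min_seg_bp=min_seg_bp, kernel_id=sid)
    report = kn.cohort_kernel_report(list(kernel_calls.values()))
    return KernelPipelineResult(schemes, cnv_calls, rgr_all, kernel_calls,
                                report)
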