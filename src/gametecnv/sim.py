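"""Synthetic single-nucleus and single-kernel sequencing simulator.

Generates the inputs the analysis side of the package consumes: a scaled
genome layout, a shared smooth amplification-bias field (a stand-in for the
locus-specific coverage distortion of whole-genome amplification), planted
per-sample maternal/paternal copy-number truths, read placements, and
per-SNP allele counts for hybrid embryo/endosperm samples.

All randomness flows from a single integer seed through
``numpy.random.default_rng``.  Coordinates are 0-based half-open
throughout, matching the BED convention used by the I/O layer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BiasField",
    "TruthEvent",
    "TruthProfile",
    "PLACEMENT_COLUMNS",
    "ROLE_BASELINES",
    "make_genome",
    "default_genome",
    "simulate_bias_field",
    "plant_pollen_truth",
    "plant_kernel_truth",
    "simulate_reads",
    "simulate_allele_counts",
    "make_snp_panel",
    "table1_line_specs",
    "build_pollen_scenario",
    "simulate_pollen_cohort",
    "simulate_cohort",
]

#: Column order for read-placement DataFrames (BED5 minus the name column,
#: which the I/O layer adds from the sample id).
PLACEMENT_COLUMNS = ("chrom", "start", "end", "mapq")

#: Baseline (maternal, paternal) genome copies per sample role.  Pollen
#: nuclei are haploid products of the male plant; their single copy is kept
#: in the "maternal" slot by convention since parental origin is
#: meaningless for them — only the total copy number enters read
#: simulation and CNV analysis.
ROLE_BASELINES: Mapping[str, tuple[int, int]] = {
    "sperm": (1, 0),
    "trophic": (1, 0),
    "microspore": (1, 0),
    "embryo": (1, 1),
    "endosperm": (2, 1),
}

VALID_ROLES = frozenset(ROLE_BASELINES)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus centromere intervals.

    The coordinate frame for every other object in the package.  The
    default test genome is a scaled-down stand-in for a ~2 Gb maize-like
    genome: 10 chromosomes totalling ~400 Mb, so that the full pipeline
    runs in minutes while every bp-denominated threshold can be scaled by
    the genome-size ratio.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for name, (cs, ce) in self.centromeres.items():
            length = dict(self.chromosomes)[name]
            if not (0 < cs < ce < length):
                raise ValueError(
                    f"centromere [{cs}, {ce}) of {name!r} not strictly inside chromosome"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


def make_genome(
    spec: Sequence[tuple[str, int]],
    centromere_fraction: float = 0.02,
    seed: int = 0,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` with seeded-random centromere placement.

    Each centromere has width ``centromere_fraction * length`` and its
    midpoint is drawn uniformly from the middle half of the chromosome,
    so centromeres never touch chromosome ends.
    """
    if not 0 < centromere_fraction < 0.5:
        raise ValueError("centromere_fraction must be in (0, 0.5)")
    for name, length in spec:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    centromeres: dict[str, tuple[int, int]] = {}
    for name, length in spec:
        width = max(1, int(round(centromere_fraction * length)))
        mid = int(rng.integers(length // 4, length - length // 4))
        start = max(1, min(mid - width // 2, length - width - 1))
        centromeres[name] = (start, start + width)
    return GenomeLayout(tuple((n, int(l)) for n, l in spec), centromeres)


#: Chromosome lengths of the default scaled test genome (bp); ~400 Mb total.
DEFAULT_CHROM_LENGTHS = (
    55_000_000, 52_000_000, 48_000_000, 45_000_000, 42_000_000,
    38_000_000, 35_000_000, 32_000_000, 28_000_000, 25_000_000,
)


def default_genome(seed: int = 0) -> GenomeLayout:
    """The 10-chromosome, ~400 Mb scaled test genome."""
    spec = [(f"chr{i + 1}", l) for i, l in enumerate(DEFAULT_CHROM_LENGTHS)]
    return make_genome(spec, centromere_fraction=0.02, seed=seed)


# ---------------------------------------------------------------------------
# Amplification-bias field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasField:
    """Piecewise-constant positive coverage multipliers on fixed tiles.

    Models the shared, locus-specific amplification/mappability bias that
    motivates uniform-depth variable binning.  Multipliers are normalized
    so the genome-wide (tile-width weighted) mean is 1.
    """

    genome: GenomeLayout
    tile_bp: int
    sigma: float
    multipliers: Mapping[str, np.ndarray]

    def tile_of(self, chrom: str, pos: np.ndarray | int):
        return np.minimum(
            np.asarray(pos) // self.tile_bp, len(self.multipliers[chrom]) - 1
        )

    def mean_multiplier(self) -> float:
        total = 0.0
        bp = 0
        for chrom, length in self.genome.chromosomes:
            mult = self.multipliers[chrom]
            widths = _tile_widths(length, self.tile_bp)
            total += float(np.sum(mult * widths))
            bp += length
        return total / bp


def _tile_widths(length: int, tile_bp: int) -> np.ndarray:
    n = math.ceil(length / tile_bp)
    widths = np.full(n, tile_bp, dtype=float)
    widths[-1] = length - (n - 1) * tile_bp
    return widths


def simulate_bias_field(
    genome: GenomeLayout,
    tile_bp: int = 100_000,
    sigma: float = 0.3,
    seed: int = 0,
    smooth_tiles: int = 5,
) -> BiasField:
    """Draw a smooth multiplicative bias field.

    Per tile, a Gaussian log-deviation is drawn, smoothed by a centred
    moving average over ``smooth_tiles`` tiles, exponentiated and then
    renormalized to a genome-wide mean multiplier of exactly 1 (within
    1e-9).  ``sigma=0`` collapses to the uniform (no-bias) model.
    """
    if tile_bp <= 0:
        raise ValueError("tile_bp must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    raw: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        n = math.ceil(length / tile_bp)
        z = rng.normal(0.0, sigma, size=n)
        if smooth_tiles > 1 and n > 1:
            kernel = np.ones(smooth_tiles) / smooth_tiles
            pad = smooth_tiles // 2
            zp = np.pad(z, pad, mode="reflect" if n > pad else "edge")
            z = np.convolve(zp, kernel, mode="valid")[:n]
        raw[chrom] = np.exp(z)
    # renormalize: weighted genome mean -> 1
    total = sum(
        float(np.sum(raw[c] * _tile_widths(l, tile_bp)))
        for c, l in genome.chromosomes
    )
    scale = genome.total_bp / total
    mult = {c: raw[c] * scale for c in raw}
    return BiasField(genome, tile_bp, sigma, mult)


# ---------------------------------------------------------------------------
# Planted copy-number truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    """One planted copy-state change on an interval."""

    chrom: str
    start: int
    end: int
    maternal_delta: int
    paternal_delta: int
    cnv_type: str | None = None  # I / II / III for sperm events, else None


@dataclass
class TruthProfile:
    """Planted per-sample maternal/paternal copy tracks.

    The oracle for every recovery test: queries return the exact copy
    number at any position, and the event list round-trips through the
    truth manifest.
    """

    sample_id: str
    role: str
    baseline_maternal: int
    baseline_paternal: int
    events: list[TruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def baseline_total(self) -> int:
        return self.baseline_maternal + self.baseline_paternal

    def validate(self, genome: GenomeLayout) -> None:
        expected = ROLE_BASELINES[self.role]
        if (self.baseline_maternal, self.baseline_paternal) != expected:
            raise ValueError(
                f"role {self.role!r} requires baseline {expected}, got "
                f"({self.baseline_maternal}, {self.baseline_paternal})"
            )
        for ev in self.events:
            length = genome.length(ev.chrom)
            if not (0 <= ev.start < ev.end <= length):
                raise ValueError(f"event {ev} outside chromosome bounds")
        for chrom in genome.names:
            _, m, p = self.copy_track(chrom, genome.length(chrom))
            if (m < 0).any() or (p < 0).any():
                raise ValueError(f"negative copy number on {chrom}")

    def copy_track(self, chrom: str, length: int):
        """Piecewise copy numbers: (bounds, maternal, paternal).

        ``bounds`` has ``k+1`` entries delimiting ``k`` segments;
        ``maternal[i]``/``paternal[i]`` are the copies on
        ``[bounds[i], bounds[i+1])``.
        """
        evs = [e for e in self.events if e.chrom == chrom]
        cuts = sorted({0, length, *(e.start for e in evs), *(e.end for e in evs)})
        bounds = np.asarray(cuts, dtype=np.int64)
        m = np.full(len(bounds) - 1, self.baseline_maternal, dtype=np.int64)
        p = np.full(len(bounds) - 1, self.baseline_paternal, dtype=np.int64)
        for e in evs:
            i0 = int(np.searchsorted(bounds, e.start))
            i1 = int(np.searchsorted(bounds, e.end))
            m[i0:i1] += e.maternal_delta
            p[i0:i1] += e.paternal_delta
        return bounds, m, p

    def copies_at(self, chrom: str, pos: int) -> tuple[int, int]:
        m = self.baseline_maternal
        p = self.baseline_paternal
        for e in self.events:
            if e.chrom == chrom and e.start <= pos < e.end:
                m += e.maternal_delta
                p += e.paternal_delta
        return m, p


def _place_interval(
    genome: GenomeLayout,
    chrom: str,
    length: int,
    centromeric: bool,
    rng: np.random.Generator,
) -> tuple[int, int]:
    chrom_len = genome.length(chrom)
    if length > chrom_len:
        raise ValueError(
            f"event length {length} exceeds chromosome {chrom!r} ({chrom_len} bp)"
        )
    if centromeric:
        cs, ce = genome.centromeres[chrom]
        mid = (cs + ce) // 2
        start = int(np.clip(mid - length // 2, 0, chrom_len - length))
    else:
        start = int(rng.integers(0, chrom_len - length + 1))
    return start, start + length


def _choose_chrom(
    genome: GenomeLayout, length: int, used: set[str], rng: np.random.Generator
) -> str:
    candidates = [
        c for c, l in genome.chromosomes if l >= length and c not in used
    ]
    if not candidates:
        candidates = [c for c, l in genome.chromosomes if l >= length]
    if not candidates:
        raise ValueError(f"no chromosome can hold an event of {length} bp")
    return candidates[int(rng.integers(len(candidates)))]


def plant_pollen_truth(
    genome: GenomeLayout,
    scenario: Sequence[Sequence[Mapping]],
    seed: int = 0,
    id_prefix: str = "pollen",
) -> list[TruthProfile]:
    """Plant sperm-pair CNVs for a list of pollen grains.

    ``scenario`` holds, per pollen, a list of event specs with keys
    ``type`` ("I", "II" or "III"), ``length`` (bp), optional ``chrom``
    (name or "random"), optional ``centromeric`` (bool), and optional
    ``sperm`` (0 or 1, the nucleus that loses the fragment).

    Type I plants copy 0 on an interval in one sperm and copy 2 on the
    identical interval in the other; type II copy 0 in one sperm only;
    type III copy 0 in both.  The trophic nucleus is always euploid.
    Returns three profiles per pollen: trophic, sperm1, sperm2.
    """
    rng = np.random.default_rng(seed)
    profiles: list[TruthProfile] = []
    for i, events in enumerate(scenario):
        pid = f"{id_prefix}{i + 1:03d}"
        trophic = TruthProfile(f"{pid}_trophic", "trophic", 1, 0)
        sperm = [
            TruthProfile(f"{pid}_sperm1", "sperm", 1, 0),
            TruthProfile(f"{pid}_sperm2", "sperm", 1, 0),
        ]
        used: set[str] = set()
        for ev in events:
            cnv_type = ev["type"]
            if cnv_type not in ("I", "II", "III"):
                raise ValueError(f"unknown CNV type {cnv_type!r}")
            length = int(ev["length"])
            chrom = ev.get("chrom", "random")
            if chrom == "random":
                chrom = _choose_chrom(genome, length, used, rng)
            used.add(chrom)
            start, end = _place_interval(
                genome, chrom, length, bool(ev.get("centromeric", False)), rng
            )
            loser = ev.get("sperm")
            loser = int(rng.integers(2)) if loser is None else int(loser)
            if cnv_type == "I":
                sperm[loser].events.append(
                    TruthEvent(chrom, start, end, -1, 0, "I"))
                sperm[1 - loser].events.append(
                    TruthEvent(chrom, start, end, +1, 0, "I"))
            elif cnv_type == "II":
                sperm[loser].events.append(
                    TruthEvent(chrom, start, end, -1, 0, "II"))
            else:  # III
                for s in sperm:
                    s.events.append(TruthEvent(chrom, start, end, -1, 0, "III"))
        for prof in (trophic, *sperm):
            prof.validate(genome)
        profiles.extend((trophic, *sperm))
    return profiles


def _complement_intervals(
    genome: GenomeLayout, retained: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in retained:
        length = genome.length(chrom)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"retained fragment {chrom}:{start}-{end} outside genome"
            )
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out: list[tuple[str, int, int]] = []
    for chrom, length in genome.chromosomes:
        pos = 0
        for s, e in sorted(by_chrom.get(chrom, [])):
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((chrom, pos, length))
    return out


def plant_kernel_truth(
    genome: GenomeLayout,
    scenario: Sequence[Mapping],
    seed: int = 0,
    id_prefix: str = "kernel",
) -> list[TruthProfile]:
    """Plant kernel truths: one embryo and one endosperm profile per kernel.

    Each scenario entry maps tissue name ("embryo", "endosperm") to a class
    spec dict with key ``class`` in {"euploid", "classI_complete",
    "classI_incomplete", "classII"}; ``classI_incomplete`` takes
    ``retained`` (list of (chrom, start, end) fragments kept from the
    eliminated parent), ``classII`` takes ``parent`` ("maternal" or
    "paternal") plus either an explicit (``chrom``, ``start``, ``end``) or
    ``length`` for random placement.  Class I eliminates the paternal
    genome unless ``parent`` says otherwise.
    """
    rng = np.random.default_rng(seed)
    profiles: list[TruthProfile] = []
    for i, kernel in enumerate(scenario):
        kid = f"{id_prefix}{i + 1:03d}"
        for tissue in ("embryo", "endosperm"):
            spec = kernel.get(tissue, {"class": "euploid"})
            bm, bp_ = ROLE_BASELINES[tissue]
            prof = TruthProfile(f"{kid}_{tissue}", tissue, bm, bp_)
            cls = spec.get("class", "euploid")
            parent = spec.get("parent", "paternal")
            dm, dp = (-1, 0) if parent == "maternal" else (0, -1)
            if cls == "euploid":
                pass
            elif cls == "classI_complete":
                for chrom, length in genome.chromosomes:
                    prof.events.append(TruthEvent(chrom, 0, length, dm, dp))
            elif cls == "classI_incomplete":
                retained = spec.get("retained", [])
                if not retained:
                    raise ValueError("classI_incomplete requires retained fragments")
                for chrom, s, e in _complement_intervals(genome, retained):
                    prof.events.append(TruthEvent(chrom, s, e, dm, dp))
            elif cls == "classII":
                if "chrom" in spec and "start" in spec:
                    chrom, s, e = spec["chrom"], int(spec["start"]), int(spec["end"])
                else:
                    length = int(spec.get("length", 20_000_000))
                    chrom = spec.get("chrom", "random")
                    if chrom == "random":
                        chrom = _choose_chrom(genome, length, set(), rng)
                    s, e = _place_interval(
                        genome, chrom, length,
                        bool(spec.get("centromeric", False)), rng)
                prof.events.append(TruthEvent(chrom, s, e, dm, dp))
            else:
                raise ValueError(f"unknown kernel class {cls!r}")
            prof.validate(genome)
            profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    truth: TruthProfile,
    bias: BiasField,
    n_reads: int,
    read_len: int = 100,
    overdispersion: float = 0.0,
    mapq_model: tuple[float, int, int] = (0.05, 5, 42),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample read placements from a planted copy-number truth.

    Read-start density is proportional to ``bias(x) * copies(x) /
    baseline``, further modulated per bias tile by an i.i.d. gamma
    multiplier with mean 1 and variance ``overdispersion`` (shape
    ``1/overdispersion``); ``overdispersion=0`` disables the modulation.
    A fraction ``low_fraction`` of reads receive the low MapQ value (the
    analysis side filters at MapQ >= 10).  Exactly ``n_reads`` placements
    are returned as a DataFrame with :data:`PLACEMENT_COLUMNS`.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if overdispersion < 0:
        raise ValueError("overdispersion must be non-negative")
    genome = bias.genome
    rng = np.random.default_rng(seed)
    low_fraction, low_value, high_value = mapq_model

    piece_chrom: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for chrom, length in genome.chromosomes:
        bounds, m, p = truth.copy_track(chrom, length)
        tile_edges = np.arange(
            bias.tile_bp, length, bias.tile_bp, dtype=np.int64)
        cuts = np.unique(np.concatenate([bounds, tile_edges]))
        seg_start = cuts[:-1]
        seg_end = cuts[1:]
        seg_copy_idx = np.searchsorted(bounds, seg_start, side="right") - 1
        copies = (m + p)[seg_copy_idx].astype(float)
        tiles = np.minimum(seg_start // bias.tile_bp,
                           len(bias.multipliers[chrom]) - 1)
        dens = bias.multipliers[chrom][tiles] * copies / truth.baseline_total
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            tile_mult = rng.gamma(shape, overdispersion,
                                  size=len(bias.multipliers[chrom]))
            dens = dens * tile_mult[tiles]
        piece_chrom.extend([chrom] * len(seg_start))
        starts.append(seg_start)
        ends.append(seg_end)
        weights.append(dens * (seg_end - seg_start))

    w = np.concatenate(weights)
    if not np.any(w > 0):
        raise ValueError("truth has total copy 0 genome-wide; nothing to sample")
    prob = w / w.sum()
    seg_starts = np.concatenate(starts)
    seg_ends = np.concatenate(ends)
    counts = rng.multinomial(n_reads, prob)

    chrom_arr = np.repeat(np.asarray(piece_chrom, dtype=object), counts)
    lo = np.repeat(seg_starts, counts)
    hi = np.repeat(seg_ends, counts)
    read_start = lo + (rng.random(n_reads) * (hi - lo)).astype(np.int64)
    chrom_len = np.fromiter(
        (genome.length(c) for c in chrom_arr), dtype=np.int64, count=n_reads)
    read_end = np.minimum(read_start + read_len, chrom_len)
    mapq = np.where(rng.random(n_reads) < low_fraction, low_value, high_value)
    return pd.DataFrame(
        {"chrom": chrom_arr, "start": read_start, "end": read_end,
         "mapq": mapq.astype(np.int64)}
    )


# ---------------------------------------------------------------------------
# SNP panel and allele counts
# ---------------------------------------------------------------------------

def make_snp_panel(
    genome: GenomeLayout, n_snps: int, seed: int = 0
) -> pd.DataFrame:
    """A biallelic parental SNP panel with positions uniform per chromosome.

    Returns a DataFrame (chrom, pos, maternal, paternal); positions are
    strictly increasing within each chromosome and alleles always differ.
    The panel size is a scaled stand-in for a multi-million-SNP parental
    panel.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = np.random.default_rng(seed)
    total = genome.total_bp
    alleles = np.array(list("ACGT"))
    frames = []
    remaining = n_snps
    for idx, (chrom, length) in enumerate(genome.chromosomes):
        if idx == len(genome.chromosomes) - 1:
            k = remaining
        else:
            k = int(round(n_snps * length / total))
            k = min(k, remaining)
        remaining -= k
        if k == 0:
            continue
        # draw with a surplus, de-duplicate, trim: avoids materializing a
        # whole-chromosome permutation for large chromosomes
        draw = rng.integers(0, length, size=int(k * 1.05) + 100)
        pos = np.unique(draw)
        while len(pos) < k:
            extra = rng.integers(0, length, size=k)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=k, replace=False)) \
            if len(pos) > k else pos
        mat = rng.integers(0, 4, size=k)
        pat = (mat + rng.integers(1, 4, size=k)) % 4
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64),
            "maternal": alleles[mat], "paternal": alleles[pat],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_allele_counts(
    truth: TruthProfile,
    panel: pd.DataFrame,
    mean_depth: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Low-depth allele counts at panel SNPs for a hybrid sample.

    Per SNP, total depth is Poisson(``mean_depth``) and the maternal count
    is Binomial(depth, m/(m+f)) where m, f are the truth's maternal and
    paternal copies at the SNP; if one parent's copies are 0 every read is
    assigned to the surviving parent, and if both are 0 the depth is 0.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    rng = np.random.default_rng(seed)
    genome_lengths = {c: 0 for c in panel["chrom"].unique()}
    m_copies = np.empty(len(panel), dtype=np.int64)
    p_copies = np.empty(len(panel), dtype=np.int64)
    for chrom in panel["chrom"].unique():
        sel = (panel["chrom"] == chrom).to_numpy()
        pos = panel.loc[sel, "pos"].to_numpy()
        bounds, m, p = truth.copy_track(chrom, int(pos.max()) + 1)
        idx = np.searchsorted(bounds, pos, side="right") - 1
        m_copies[sel] = m[idx]
        p_copies[sel] = p[idx]
    total = m_copies + p_copies
    depth = rng.poisson(mean_depth, size=len(panel))
    depth = np.where(total == 0, 0, depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, m_copies / np.maximum(total, 1), 0.0)
    maternal = rng.binomial(depth, frac)
    paternal = depth - maternal
    return pd.DataFrame({
        "chrom": panel["chrom"].to_numpy(),
        "pos": panel["pos"].to_numpy(),
        "maternal_count": maternal.astype(np.int64),
        "paternal_count": paternal.astype(np.int64),
    })


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def table1_line_specs() -> list[dict]:
    """The study-shaped default cohort: per-line pollen counts and planted
    aneuploidy composition (pollens with one / two aneuploid sperm)."""
    return [
        {"name": "CAU5", "group": "inducer", "n_pollen": 22,
         "nuclei_per_pollen": 3, "one_aneuploid": 3, "two_aneuploid": 3},
        {"name": "B73", "group": "regular", "n_pollen": 25,
         "nuclei_per_pollen": 2, "one_aneuploid": 3, "two_aneuploid": 0},
        {"name": "B73-inducer", "group": "inducer", "n_pollen": 26,
         "nuclei_per_pollen": 2, "one_aneuploid": 4, "two_aneuploid": 5},
        {"name": "Chang7-2", "group": "regular", "n_pollen": 33,
         "nuclei_per_pollen": 2, "one_aneuploid": 1, "two_aneuploid": 1},
        {"name": "CHOI3", "group": "inducer", "n_pollen": 35,
         "nuclei_per_pollen": 2, "one_aneuploid": 4, "two_aneuploid": 2},
    ]


DEFAULT_COHORT_CONFIG: dict = {
    "genome": {
        "lengths": list(DEFAULT_CHROM_LENGTHS),
        "centromere_fraction": 0.02,
    },
    "reads_per_nucleus": 200_000,
    "read_len": 100,
    "bias": {"tile_bp": 100_000, "sigma": 0.3, "smooth_tiles": 5},
    "overdispersion": 0.05,
    "mapq": {"low_fraction": 0.05, "low_value": 5, "high_value": 42},
    "event_length_range": [8_000_000, 20_000_000],
    "centromeric_fraction": 0.5,
    "lines": table1_line_specs(),
}


def build_pollen_scenario(
    line_cfg: Mapping,
    genome: GenomeLayout,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (8_000_000, 20_000_000),
    centromeric_fraction: float = 0.5,
) -> tuple[list, list[str]]:
    """Turn a per-line spec into an explicit pollen event scenario.

    Pollens with exactly one aneuploid sperm carry type II events (a loss
    in one sperm only); pollens with two aneuploid sperm carry a type I
    (complementary loss/gain) or type III (loss in both) event, chosen at
    random, occasionally with an extra type II on the same loser.  Events
    overlap the centromere with probability ``centromeric_fraction``,
    reflecting the concentration of sperm CNVs in pericentromeric regions.
    Returns (scenario, expected category per pollen).
    """
    n = int(line_cfg["n_pollen"])
    n1 = int(line_cfg.get("one_aneuploid", 0))
    n2 = int(line_cfg.get("two_aneuploid", 0))
    if n1 + n2 > n:
        raise ValueError("more aneuploid pollens than pollens")
    categories = (["one_aneuploid_sperm"] * n1 + ["two_aneuploid_sperm"] * n2
                  + ["euploid"] * (n - n1 - n2))
    rng.shuffle(categories)
    lo, hi = int(length_range[0]), int(length_range[1])

    def _event(cnv_type, sperm=None):
        return {
            "type": cnv_type,
            "length": int(rng.integers(lo, hi + 1)),
            "chrom": "random",
            "centromeric": bool(rng.random() < centromeric_fraction),
            "sperm": sperm,
        }

    scenario = []
    for cat in categories:
        if cat == "euploid":
            scenario.append([])
        elif cat == "one_aneuploid_sperm":
            loser = int(rng.integers(2))
            events = [_event("II", loser)]
            if rng.random() < 0.3:
                events.append(_event("II", loser))
            scenario.append(events)
        else:
            main = "I" if rng.random() < 0.5 else "III"
            events = [_event(main)]
            if rng.random() < 0.3:
                events.append(_event("II"))
            scenario.append(events)
    return scenario, categories


def simulate_pollen_cohort(config: Mapping | None = None, seed: int = 0):
    """In-memory cohort simulation.

    Returns ``(genome, sample_table, placements, truths)`` where
    ``sample_table`` is a DataFrame (sample_id, unit_id, role, line,
    group, category), ``placements`` maps sample id to a placement
    DataFrame and ``truths`` maps sample id to its :class:`TruthProfile`.
    """
    cfg = dict(DEFAULT_COHORT_CONFIG)
    if config:
        cfg.update(config)
    master = np.random.default_rng(seed)
    gcfg = cfg["genome"]
    genome = make_genome(
        [(f"chr{i + 1}", int(l)) for i, l in enumerate(gcfg["lengths"])],
        centromere_fraction=gcfg.get("centromere_fraction", 0.02),
        seed=int(master.integers(2**31)),
    )
    bias = simulate_bias_field(
        genome,
        tile_bp=int(cfg["bias"]["tile_bp"]),
        sigma=float(cfg["bias"]["sigma"]),
        smooth_tiles=int(cfg["bias"].get("smooth_tiles", 5)),
        seed=int(master.integers(2**31)),
    )
    rows = []
    placements: dict[str, pd.DataFrame] = {}
    truths: dict[str, TruthProfile] = {}
    for line_cfg in cfg["lines"]:
        line = line_cfg["name"]
        rng = np.random.default_rng(int(master.integers(2**31)))
        scenario, categories = build_pollen_scenario(
            line_cfg, genome, rng,
            length_range=tuple(cfg["event_length_range"]),
            centromeric_fraction=float(cfg.get("centromeric_fraction", 0.5)),
        )
        prefix = line.replace(" ", "_") + "_pollen"
        profiles = plant_pollen_truth(
            genome, scenario, seed=int(rng.integers(2**31)), id_prefix=prefix)
        nuclei = int(line_cfg.get("nuclei_per_pollen", 2))
        for i in range(len(scenario)):
            trio = profiles[3 * i: 3 * i + 3]
            kept = trio if nuclei == 3 else trio[1:]
            unit = f"{prefix}{i + 1:03d}"
            for prof in kept:
                reads = simulate_reads(
                    prof, bias,
                    n_reads=int(cfg["reads_per_nucleus"]),
                    read_len=int(cfg["read_len"]),
                    overdispersion=float(cfg["overdispersion"]),
                    mapq_model=(
                        float(cfg["mapq"]["low_fraction"]),
                        int(cfg["mapq"]["low_value"]),
                        int(cfg["mapq"]["high_value"]),
                    ),
                    seed=int(rng.integers(2**31)),
                )
                placements[prof.sample_id] = reads
                truths[prof.sample_id] = prof
                rows.append({
                    "sample_id": prof.sample_id, "unit_id": unit,
                    "role": prof.role, "line": line,
                    "group": line_cfg["group"], "category": categories[i],
                })
    sample_table = pd.DataFrame(rows)
    return genome, sample_table, placements, truths


DEFAULT_KERNEL_CONFIG: dict = {
    "genome": {
        "lengths": list(DEFAULT_CHROM_LENGTHS),
        "centromere_fraction": 0.02,
    },
    "reads_per_sample": 200_000,
    "read_len": 100,
    "bias": {"tile_bp": 100_000, "sigma": 0.3, "smooth_tiles": 5},
    "overdispersion": 0.05,
    "mapq": {"low_fraction": 0.05, "low_value": 5, "high_value": 42},
    # parental-panel SNP density matches the full-scale study (~1.45
    # SNPs/kb), so 700-SNP bins span ~500 kb on the scaled genome too
    "n_snps": 580_000,
    "mean_depth": 1.0,
}


def simulate_kernel_cohort(
    scenario: Sequence[Mapping], config: Mapping | None = None, seed: int = 0
):
    """Simulate a kernel cohort: reads and allele counts per tissue sample.

    ``scenario`` is the per-kernel class spec understood by
    :func:`plant_kernel_truth`.  Returns ``(genome, samples, placements,
    allele_counts, truths, panel)`` where ``samples`` has columns
    (sample_id, unit_id, role, line, group).
    """
    cfg = dict(DEFAULT_KERNEL_CONFIG)
    if config:
        cfg.update(config)
    master = np.random.default_rng(seed)
    gcfg = cfg["genome"]
    genome = make_genome(
        [(f"chr{i + 1}", int(l)) for i, l in enumerate(gcfg["lengths"])],
        centromere_fraction=gcfg.get("centromere_fraction", 0.02),
        seed=int(master.integers(2**31)),
    )
    bias = simulate_bias_field(
        genome,
        tile_bp=int(cfg["bias"]["tile_bp"]),
        sigma=float(cfg["bias"]["sigma"]),
        smooth_tiles=int(cfg["bias"].get("smooth_tiles", 5)),
        seed=int(master.integers(2**31)),
    )
    panel = make_snp_panel(genome, int(cfg["n_snps"]),
                           seed=int(master.integers(2**31)))
    profiles = plant_kernel_truth(genome, scenario,
                                  seed=int(master.integers(2**31)))
    rows = []
    placements: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.DataFrame] = {}
    truths: dict[str, TruthProfile] = {}
    for prof in profiles:
        placements[prof.sample_id] = simulate_reads(
            prof, bias,
            n_reads=int(cfg["reads_per_sample"]),
            read_len=int(cfg["read_len"]),
            overdispersion=float(cfg["overdispersion"]),
            mapq_model=(
                float(cfg["mapq"]["low_fraction"]),
                int(cfg["mapq"]["low_value"]),
                int(cfg["mapq"]["high_value"]),
            ),
            seed=int(master.integers(2**31)),
        )
        counts[prof.sample_id] = simulate_allele_counts(
            prof, panel, mean_depth=float(cfg["mean_depth"]),
            seed=int(master.integers(2**31)),
        )
        truths[prof.sample_id] = prof
        rows.append({
            "sample_id": prof.sample_id,
            "unit_id": prof.sample_id.rsplit("_", 1)[0],
            "role": prof.role, "line": "F1", "group": "kernel",
        })
    return genome, pd.DataFrame(rows), placements, counts, truths, panel


def simulate_cohort(
    config: Mapping | None, outdir, seed: int = 0
) -> pd.DataFrame:
    """Simulate a cohort and write it to ``outdir`` as plain-text files.

    Writes per-sample BED5 placements, a sample sheet TSV, a genome TSV +
    centromere BED, and a truth manifest TSV (one row per planted event,
    plus per-sample role/category rows).  Fully reproducible: the same
    config and seed give byte-identical output.  Returns the sample sheet.
    """
    from . import io as fio  # local import: io depends on sim types

    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, samples, placements, truths = simulate_pollen_cohort(config, seed)
    fio.write_genome(genome, out / "genome.tsv", out / "centromeres.bed")
    placement_dir = out / "placements"
    placement_dir.mkdir(exist_ok=True)
    paths = []
    for sid in samples["sample_id"]:
        path = placement_dir / f"{sid}.bed"
        fio.write_placements(placements[sid], path, name=sid)
        paths.append(str(path.relative_to(out)))
    sheet = samples.copy()
    sheet["placements_path"] = paths
    sheet["seed"] = seed
    fio.write_report(sheet, out / "samples.tsv")
    manifest_rows = []
    for sid, prof in truths.items():
        if not prof.events:
            manifest_rows.append({
                "sample_id": sid, "role": prof.role, "chrom": ".",
                "start": -1, "end": -1, "maternal_delta": 0,
                "paternal_delta": 0, "cnv_type": ".",
            })
        for e in prof.events:
            manifest_rows.append({
                "sample_id": sid, "role": prof.role, "chrom": e.chrom,
                "start": e.start, "end": e.end,
                "maternal_delta": e.maternal_delta,
                "paternal_delta": e.paternal_delta,
                "cnv_type": e.cnv_type or ".",
            })
    fio.write_report(pd.DataFrame(manifest_rows), out / "truth_manifest.tsv")
    return sheet
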