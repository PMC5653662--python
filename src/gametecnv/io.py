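"""Readers and writers for every on-disk artifact.

Dialects
--------
* read placements: BED5 (chrom, start, end, name=sample id, score=MapQ
  clamped to 0-60);
* bins / segments: BED3 plus a TSV sidecar for per-bin values;
* SNP panel: minimal VCF (REF = maternal allele, ALT = paternal allele,
  by convention stated in the header) or a 4-column TSV;
* allele counts, sample sheets, reports, truth manifests: TSV.

Every genomic interval is 0-based half-open (BED convention).  All
writers are deterministic and write->read->write is byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import VALID_ROLES, GenomeLayout

logger = logging.getLogger("gametecnv")

__all__ = [
    "Dataset",
    "read_placements",
    "write_placements",
    "read_genome",
    "write_genome",
    "read_snp_panel",
    "write_snp_panel_tsv",
    "write_snp_panel_vcf",
    "read_allele_counts",
    "write_allele_counts",
    "write_bins",
    "read_bins",
    "write_segments",
    "write_report",
    "read_report",
    "load_dataset",
]


class ParseError(ValueError):
    """Malformed on-disk record, with file/line context."""


# ---------------------------------------------------------------------------
# Read placements (BED5)
# ---------------------------------------------------------------------------

def write_placements(placements: pd.DataFrame, path, name: str = ".") -> None:
    """Write placements as BED5; the score column carries MapQ (0-60)."""
    df = placements[["chrom", "start", "end", "mapq"]].copy()
    df["name"] = name
    df["score"] = df.pop("mapq").clip(0, 60)
    df[["chrom", "start", "end", "name", "score"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_placements(path, mapq_min: int = 10) -> pd.DataFrame:
    """Read BED5 placements, keeping records with MapQ >= ``mapq_min``.

    Input order is preserved.  Malformed lines raise :class:`ParseError`
    with the 1-based line number; kept/dropped counts are logged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 BED columns")
            chrom, s, e, _name, score = parts[:5]
            try:
                start, end, mapq = int(s), int(e), int(score)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate or score") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start, end, mapq))
    total = len(rows)
    kept = [r for r in rows if r[3] >= mapq_min]
    if total == 0:
        logger.warning("%s: empty placement file", path)
    logger.info("%s: kept %d / dropped %d reads (MapQ >= %d)",
                path, len(kept), total - len(kept), mapq_min)
    return pd.DataFrame(kept, columns=["chrom", "start", "end", "mapq"])


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeLayout, layout_path, centromere_path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        layout_path, sep="\t", index=False)
    rows = [(c, s, e) for c, (s, e) in genome.centromeres.items()]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        centromere_path, sep="\t", header=False, index=False)


def read_genome(layout_path, centromere_path) -> GenomeLayout:
    layout = pd.read_csv(layout_path, sep="\t")
    cen = pd.read_csv(centromere_path, sep="\t", header=None,
                      names=["chrom", "start", "end"])
    centromeres = {r.chrom: (int(r.start), int(r.end))
                   for r in cen.itertuples()}
    return GenomeLayout(
        tuple((r.chrom, int(r.length)) for r in layout.itertuples()),
        centromeres)


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

def _check_panel_sorted(panel: pd.DataFrame, origin: str) -> None:
    for chrom, sub in panel.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        bad = np.nonzero(np.diff(pos) <= 0)[0]
        if bad.size:
            raise ParseError(
                f"{origin}: SNP positions not strictly increasing on "
                f"{chrom} at pos {pos[bad[0] + 1]}")


def write_snp_panel_tsv(panel: pd.DataFrame, path) -> None:
    panel[["chrom", "pos", "maternal", "paternal"]].to_csv(
        path, sep="\t", index=False)


def write_snp_panel_vcf(panel: pd.DataFrame, genome: GenomeLayout, path) -> None:
    """Minimal biallelic VCF; REF is the maternal allele by convention."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##REF=maternal allele, ALT=paternal allele (by convention)\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in panel.itertuples():
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.maternal}\t"
                     f"{r.paternal}\t.\tPASS\t.\n")


def read_snp_panel(path) -> pd.DataFrame:
    """Read a SNP panel from minimal VCF (``.vcf``) or 4-column TSV.

    Only biallelic SNP records are accepted from VCF; INFO/FORMAT are
    ignored.  Positions are returned 0-based and must be strictly
    increasing per chromosome.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        from cyvcf2 import VCF

        rows = []
        for v in VCF(str(path)):
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                raise ParseError(
                    f"{path}: non-biallelic-SNP record at {v.CHROM}:{v.POS}")
            rows.append((v.CHROM, v.start, v.REF, v.ALT[0]))
        panel = pd.DataFrame(rows, columns=["chrom", "pos", "maternal", "paternal"])
    else:
        panel = pd.read_csv(path, sep="\t")
        panel = panel[["chrom", "pos", "maternal", "paternal"]]
    if (panel["maternal"] == panel["paternal"]).any():
        raise ParseError(f"{path}: SNP with identical parental alleles")
    _check_panel_sorted(panel, str(path))
    return panel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def write_allele_counts(counts: pd.DataFrame, path, sample_id: str) -> None:
    df = counts[["chrom", "pos", "maternal_count", "paternal_count"]].copy()
    df.insert(0, "sample", sample_id)
    df.to_csv(path, sep="\t", index=False)


def read_allele_counts(path, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read per-SNP allele counts; optionally enforce panel membership."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "maternal_count", "paternal_count"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df[["maternal_count", "paternal_count"]] < 0).any().any():
        raise ParseError(f"{path}: negative allele count")
    if panel is not None:
        key = pd.MultiIndex.from_frame(panel[["chrom", "pos"]])
        here = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        orphan = ~here.isin(key)
        if orphan.any():
            row = df[orphan].iloc[0]
            raise ParseError(
                f"{path}: allele counts at {row.chrom}:{row.pos} reference a "
                "SNP absent from the panel")
    return df


# ---------------------------------------------------------------------------
# Bins, segments, reports
# ---------------------------------------------------------------------------

def write_bins(scheme, bed_path, sidecar_path=None) -> None:
    """Write a bin scheme as BED3; per-bin pooled counts and mask flags go
    to an optional TSV sidecar."""
    scheme.bins[["chrom", "start", "end"]].to_csv(
        bed_path, sep="\t", header=False, index=False)
    if sidecar_path is not None:
        side = scheme.bins[["chrom", "start", "end"]].copy()
        side["pooled_count"] = (
            scheme.pooled_counts if scheme.pooled_counts is not None else -1)
        side["masked"] = scheme.masked.astype(int)
        side.to_csv(sidecar_path, sep="\t", index=False)


def read_bins(bed_path) -> pd.DataFrame:
    return pd.read_csv(bed_path, sep="\t", header=None,
                       names=["chrom", "start", "end"])


def write_segments(calls, path) -> None:
    """Write per-nucleus segments as a BED-like TSV.

    Intervals are 0-based half-open, exactly as computed.  ``calls`` is an
    iterable of NucleusCall objects.
    """
    rows = []
    for call in calls:
        for seg in call.segments:
            rows.append((seg.chrom, seg.start, seg.end, call.sample_id,
                         seg.copy_state, round(seg.mean_log2, 6), seg.n_bins,
                         int(seg.centromere_overlap)))
    pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "sample", "copy_state", "mean_log2",
        "n_bins", "centromere_overlap",
    ]).to_csv(path, sep="\t", index=False)


def write_report(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A cohort on disk: genome, sample sheet and per-sample file paths."""

    genome: GenomeLayout
    samples: pd.DataFrame
    root: Path

    def placements_path(self, sample_id: str) -> Path:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        return self.root / row["placements_path"].iloc[0]

    def validate(self) -> None:
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            raise ValueError(
                f"duplicate sample id {ids[ids.duplicated()].iloc[0]!r}")
        bad_roles = set(self.samples["role"]) - VALID_ROLES
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")
        for col in ("placements_path", "allele_counts_path"):
            if col not in self.samples.columns:
                continue
            for p in self.samples[col].dropna():
                if not (self.root / p).exists():
                    raise FileNotFoundError(self.root / p)


def load_dataset(root) -> Dataset:
    """Load a simulated or hand-built cohort directory and validate it."""
    root = Path(root)
    genome = read_genome(root / "genome.tsv", root / "centromeres.bed")
    samples = read_report(root / "samples.tsv")
    ds = Dataset(genome, samples, root)
    ds.validate()
    return ds
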