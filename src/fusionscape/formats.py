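"""Core containers and readers/writers for the standard formats the pipeline touches.

Conventions
-----------
All internal coordinates are 0-based half-open.  User-facing region strings
(``chr2:113940058-114049496``) are 1-based inclusive, matching how genomic
coordinates are printed in browsers and papers; :func:`parse_region_string`
and :func:`format_region_string` convert between the two and are involutive.

FASTA goes through Biopython, VCF reading through pysam, and Newick through
dendropy; BED, PAF and bedMethyl are simple tab formats handled directly.
All readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import Clade, from_newick

logger = logging.getLogger(__name__)

MISSING = -1  # missing haplotype call in a VariantMatrix


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open span on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


_REGION_RE = re.compile(r"^(?P<name>[^:]+):(?P<start>[\d,]+)[-–](?P<end>[\d,]+)$")


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``name:start-end`` region into a half-open interval.

    Both ASCII hyphen and en-dash separators are accepted (papers print
    en-dashes); thousands separators are tolerated.
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed region string: {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or start1 > end1:
        raise ValueError(f"invalid 1-based coordinates in {text!r}")
    return GenomicInterval(m.group("name"), start1 - 1, end1)


def format_region_string(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive output)."""
    return f"{iv.seq_name}:{iv.start + 1}-{iv.end}"


@dataclass
class WindowAlignment:
    """One orthologous alignment window: equal-length sequences keyed by taxon."""

    sequences: dict[str, str]

    def __post_init__(self):
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def subset(self, taxa) -> "WindowAlignment":
        return WindowAlignment({t: self.sequences[t] for t in taxa})


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment record (block-level subset; cg/dv tags kept if present)."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int
    tags: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError("query coordinates out of range")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError("target coordinates out of range")
        if self.matches > self.block_len:
            raise ValueError("matches exceed block length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0


@dataclass(frozen=True)
class BedMethylRecord:
    interval: GenomicInterval
    coverage: int
    frequency: float

    def __post_init__(self):
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"methylation frequency {self.frequency} not in [0,1]")
        if self.coverage < 0:
            raise ValueError("negative coverage")


@dataclass
class MethylTrack:
    """Per-site (or per-interval) methylation frequencies on one sequence."""

    seq_name: str
    starts: np.ndarray  # 0-based
    ends: np.ndarray
    frequency: np.ndarray  # in [0, 1]
    coverage: np.ndarray | None = None

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.coverage is None:
            self.coverage = np.ones(len(self.starts), dtype=np.int64)
        else:
            self.coverage = np.asarray(self.coverage, dtype=np.int64)
        n = len(self.starts)
        if not (len(self.ends) == len(self.frequency) == len(self.coverage) == n):
            raise ValueError("track arrays have inconsistent lengths")
        if n and (self.frequency.min() < 0 or self.frequency.max() > 1):
            raise ValueError("methylation frequencies outside [0,1]")

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2

    def __len__(self) -> int:
        return len(self.starts)

    def to_records(self) -> list[BedMethylRecord]:
        return [
            BedMethylRecord(
                GenomicInterval(self.seq_name, int(s), int(e)), int(c), float(f)
            )
            for s, e, f, c in zip(self.starts, self.ends, self.frequency, self.coverage)
        ]


@dataclass
class VariantMatrix:
    """Biallelic haplotype panel: samples x sorted sites over {0, 1, MISSING}."""

    samples: list[str]
    positions: np.ndarray  # 0-based site positions, strictly increasing
    genotypes: np.ndarray  # shape (n_haplotypes, n_sites), int8
    seq_name: str = "chrS"
    seq_len: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.genotypes.shape != (len(self.samples), len(self.positions)):
            raise ValueError("genotype matrix shape inconsistent with labels")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


# ---------------------------------------------------------------------------
# file helpers
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """Malformed input; carries the offending line number when known."""


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# -- BED --------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    last_by_chrom: dict[str, int] = {}
    unsorted = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
            if start < last_by_chrom.get(chrom, 0):
                unsorted = True
            last_by_chrom[chrom] = start
    if unsorted:
        logger.warning("BED file %s is not coordinate-sorted", path)
    return out


def write_bed(intervals, path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.seq_name, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                fields.append(iv.name or ".")
            if iv.strand != ".":
                fields.extend(["0", iv.strand])
            fh.write("\t".join(fields) + "\n")


# -- PAF --------------------------------------------------------------------

_PAF_TAG_TYPES = {"i": int, "f": float, "A": str, "Z": str}


def read_paf(path) -> list[PafRecord]:
    out: list[PafRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"line {lineno}: expected >=12 PAF columns")
            try:
                tags = {}
                for tag in fields[12:]:
                    key, typ, value = tag.split(":", 2)
                    tags[key] = _PAF_TAG_TYPES.get(typ, str)(value)
                out.append(
                    PafRecord(
                        query_name=fields[0],
                        query_len=int(fields[1]),
                        query_start=int(fields[2]),
                        query_end=int(fields[3]),
                        strand=fields[4],
                        target_name=fields[5],
                        target_len=int(fields[6]),
                        target_start=int(fields[7]),
                        target_end=int(fields[8]),
                        matches=int(fields[9]),
                        block_len=int(fields[10]),
                        mapq=int(fields[11]),
                        tags=tags,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return out


def write_paf(records, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fields = [
                r.query_name, str(r.query_len), str(r.query_start), str(r.query_end),
                r.strand,
                r.target_name, str(r.target_len), str(r.target_start), str(r.target_end),
                str(r.matches), str(r.block_len), str(r.mapq),
            ]
            for key, value in r.tags.items():
                typ = "i" if isinstance(value, int) else "f" if isinstance(value, float) else "Z"
                fields.append(f"{key}:{typ}:{value}")
            fh.write("\t".join(fields) + "\n")


# -- bedMethyl --------------------------------------------------------------

def read_bedmethyl(path) -> MethylTrack:
    chroms, starts, ends, covs, freqs = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"line {lineno}: expected 5 bedMethyl columns")
            try:
                chroms.append(fields[0])
                starts.append(int(fields[1]))
                ends.append(int(fields[2]))
                covs.append(int(fields[3]))
                freqs.append(float(fields[4]))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    if len(set(chroms)) > 1:
        raise FormatError("bedMethyl track spans multiple sequences")
    return MethylTrack(
        seq_name=chroms[0] if chroms else "chrS",
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        frequency=np.array(freqs, dtype=float),
        coverage=np.array(covs, dtype=np.int64),
    )


def write_bedmethyl(track: MethylTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for s, e, c, f in zip(track.starts, track.ends, track.coverage, track.frequency):
            fh.write(f"{track.seq_name}\t{s}\t{e}\t{c}\t{f:.6g}\n")


# -- Newick -----------------------------------------------------------------

def read_newick(path) -> Clade:
    with _open_text(path) as fh:
        return from_newick(fh.read())


def write_newick(tree: Clade, path, precision: int = 10) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(tree.newick(precision=precision) + "\n")


# -- minimal VCF (GT-only) --------------------------------------------------

def write_vcf(vm: VariantMatrix, path, ploidy: int = 2) -> None:
    """Write a minimal GT-only VCF.

    With ``ploidy=2`` consecutive haplotypes are paired into phased diploid
    samples (requires an even haplotype count); ``ploidy=1`` writes one
    haploid sample per haplotype.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    n = vm.n_haplotypes
    if ploidy == 2 and n % 2:
        raise ValueError("diploid output needs an even number of haplotypes")
    seq_len = vm.seq_len or (int(vm.positions[-1]) + 1 if vm.n_sites else 1)
    if ploidy == 2:
        sample_names = [f"{vm.samples[i]}_{vm.samples[i + 1]}" for i in range(0, n, 2)]
    else:
        sample_names = list(vm.samples)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={vm.seq_name},length={seq_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for j in range(vm.n_sites):
            col = vm.genotypes[:, j]
            alleles = ["." if g == MISSING else str(int(g)) for g in col]
            if ploidy == 2:
                gts = [f"{alleles[i]}|{alleles[i + 1]}" for i in range(0, n, 2)]
            else:
                gts = alleles
            fh.write(
                f"{vm.seq_name}\t{int(vm.positions[j]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path, skip_multiallelic: bool = True) -> VariantMatrix:
    """Read a GT-only VCF into a haplotype matrix (phased GTs are split)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    positions: list[int] = []
    rows: list[list[int]] = []
    seq_name = None
    hap_names: list[str] | None = None
    for rec in vf.fetch() if vf.index is not None else vf:
        if len(rec.alts or ()) != 1:
            if skip_multiallelic:
                logger.warning("skipping multiallelic site at %s:%d", rec.chrom, rec.pos)
                continue
            raise FormatError(f"multiallelic site at {rec.chrom}:{rec.pos}")
        seq_name = seq_name or rec.chrom
        calls: list[int] = []
        names: list[str] = []
        for s in sample_names:
            gt = rec.samples[s]["GT"]
            for k, allele in enumerate(gt):
                calls.append(MISSING if allele is None else int(allele))
                names.append(f"{s}.{k}" if len(gt) > 1 else s)
        if hap_names is None:
            hap_names = names
        positions.append(rec.pos - 1)
        rows.append(calls)
    n_haps = len(hap_names) if hap_names else len(sample_names)
    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((n_haps, 0), dtype=np.int8)
    )
    lengths = {c.name: c.length for c in vf.header.contigs.values()}
    return VariantMatrix(
        samples=hap_names or sample_names,
        positions=np.array(positions, dtype=np.int64),
        genotypes=genotypes,
        seq_name=seq_name or "chrS",
        seq_len=lengths.get(seq_name),
    )
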