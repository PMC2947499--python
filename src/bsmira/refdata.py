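"""Reference sequences, annotation tracks, and CpG-site discovery.

Every downstream stage (simulation, alignment, methylation calling,
annotation) works on the containers defined here.  All coordinates are
0-based half-open throughout the package; BED input/output passes through
unchanged, and any 1-based display is presentation-layer only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files or invalid coordinates."""


@dataclass
class ReferenceGenome:
    """Named chromosome sequences (upper-case A/C/G/T/N only).

    ``chromosomes`` preserves insertion order; names are unique.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    ``strand`` is '+', '-' or '.' (unstranded); ``name`` is an optional
    label (BED column 4, also used to carry repeat classes).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Minimal refFlat-style gene model (name, chrom, strand, txStart, txEnd)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.name}: invalid strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise FormatError(f"gene {self.name}: txStart must be < txEnd")

    @property
    def tss(self) -> int:
        """Transcription start: txStart on '+', txEnd on '-' (as a coordinate)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


@dataclass
class AnnotationSet:
    """Gene models, CpG islands and repeat intervals for one genome."""

    genes: list[GeneModel] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    repeats: list[tuple[GenomicInterval, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> ReferenceGenome:
    """Load a FASTA file into a ReferenceGenome (lowercase normalized)."""
    chroms: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    for rec in records:
        if rec.id in chroms:
            raise FormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq).upper()
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path, genome: ReferenceGenome | None = None) -> list[GenomicInterval]:
    """Read a BED3/BED4(+) file into half-open intervals.

    The fourth column, when present, becomes the interval name (used for
    CGI labels and repeat classes).  Column 6, when present, is the strand.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand, name)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                if chrom not in genome:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise FormatError(
                        f"{path}:{lineno}: interval extends past end of {chrom}"
                    )
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED (3, 4 or 6 columns depending on content)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand != ".":
                cols.extend(["0", iv.strand])
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read a tab-separated gene table: name, chrom, strand, txStart, txEnd."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                genes.append(
                    GeneModel(cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]))
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


# ---------------------------------------------------------------------------
# CpG sites and interval queries
# ---------------------------------------------------------------------------


def find_cpg_sites(genome: ReferenceGenome) -> list[tuple[str, int]]:
    """All CpG dinucleotides, recorded once at the forward-strand C.

    Returned sorted by (chromosome order of the genome, position).  A site
    is a position ``pos`` with seq[pos] == 'C' and seq[pos+1] == 'G'; any
    N in either base excludes the site.
    """
    sites: list[tuple[str, int]] = []
    for name, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            continue
        hits = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        sites.extend((name, int(p)) for p in hits)
    return sites


def scan_cpg_positions(seq: str) -> list[int]:
    """CpG positions in a single sequence (regex scan; oracle-friendly)."""
    return [m.start() for m in re.finditer("(?=CG)", seq)]


class IntervalIndex:
    """Per-chromosome interval tree for overlap queries.

    Query results carry whatever payload was supplied at build time (the
    interval itself by default).
    """

    def __init__(self, intervals: Iterable[tuple[GenomicInterval, object]] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        if intervals is not None:
            for iv, payload in intervals:
                self.add(iv, payload)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        idx = cls()
        for iv in intervals:
            idx.add(iv, iv)
        return idx

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)

    def query(self, chrom: str, start: int, end: int) -> list[object]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))

    def __iter__(self) -> Iterator[object]:
        for tree in self._trees.values():
            for hit in tree:
                yield hit.data
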