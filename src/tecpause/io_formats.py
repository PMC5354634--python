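"""Genomics file formats and the concatenated transcription-oriented coordinate system.

Every downstream computation (energy profiles, pause calling, PWM scoring,
backtrack classification) runs on a single coordinate axis: all considered
genes concatenated in input order, each written 5'->3' on its coding strand
(minus-strand genes reverse-complemented).  This module builds that axis and
reads/writes the standard flat formats around it: FASTA genomes, BED6 gene
intervals, 4-column bedGraph coverage and TSV nucleosome-center tables.

Internal coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: base -> integer code used by vectorized scoring (4 marks N / unknown)
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a genomic interval (0-based half-open) with a strand."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.name!r}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name!r}: strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ConcatenatedTranscriptome:
    """All considered genes concatenated in coding-strand orientation.

    ``boundaries`` has one entry per gene plus a terminal sentinel, so gene
    ``g`` occupies concatenated positions ``boundaries[g]:boundaries[g+1]``.
    """

    sequence: str
    genes: list[GeneInterval]
    boundaries: np.ndarray
    gene_id: np.ndarray = field(repr=False)  # int32 per position
    codes: np.ndarray = field(repr=False)  # uint8 per position, 0..3 (4 = N)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_of(self, pos: int) -> int:
        """Index of the gene containing concatenated position ``pos``."""
        if not 0 <= pos < len(self):
            raise IndexError(f"position {pos} outside transcriptome of length {len(self)}")
        return int(np.searchsorted(self.boundaries, pos, side="right") - 1)

    def to_concat(self, gene: int, offset: int) -> int:
        """Map (gene index, transcript offset) -> concatenated position."""
        g = self.genes[gene]
        if not 0 <= offset < len(g):
            raise IndexError(f"offset {offset} outside gene {gene} of length {len(g)}")
        return int(self.boundaries[gene]) + offset

    def to_gene(self, pos: int) -> tuple[int, int]:
        """Map concatenated position -> (gene index, transcript offset)."""
        g = self.gene_of(pos)
        return g, pos - int(self.boundaries[g])

    def to_genomic(self, pos: int) -> tuple[str, int, str]:
        """Map concatenated position -> (chrom, genomic position, strand)."""
        g, off = self.to_gene(pos)
        gene = self.genes[g]
        if gene.strand == "+":
            return gene.chrom, gene.start + off, "+"
        return gene.chrom, gene.end - 1 - off, "-"

    def from_genomic(self, chrom: str, gpos: int, strand: str) -> int | None:
        """Inverse of :meth:`to_genomic`; None if (chrom, gpos, strand) is in no gene."""
        for g, gene in enumerate(self.genes):
            if gene.chrom == chrom and gene.strand == strand and gene.start <= gpos < gene.end:
                off = gpos - gene.start if strand == "+" else gene.end - 1 - gpos
                return int(self.boundaries[g]) + off
        return None

    def genomic_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-position (gene index, genomic coordinate) arrays for the whole axis."""
        gpos = np.empty(len(self), dtype=np.int64)
        for g, gene in enumerate(self.genes):
            lo, hi = int(self.boundaries[g]), int(self.boundaries[g + 1])
            if gene.strand == "+":
                gpos[lo:hi] = np.arange(gene.start, gene.end)
            else:
                gpos[lo:hi] = np.arange(gene.end - 1, gene.start - 1, -1)
        return self.gene_id, gpos


@dataclass
class CoverageTrack:
    """Per-position 3'-end read counts on the concatenated transcriptome."""

    counts: np.ndarray
    strain: str = "other"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: upper-case sequence}``.

    The record id is the token before the first whitespace.  Sequences are
    restricted to A/C/G/T/N after upper-casing; anything else raises with the
    offending record and position.
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def _finish():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"FASTA record {name!r} is empty")
        bad = next((i for i, c in enumerate(seq) if c not in "ACGTN"), None)
        if bad is not None:
            raise ValueError(f"FASTA record {name!r}: non-IUPAC character {seq[bad]!r} at position {bad}")
        records[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _finish()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
    _finish()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED genes

def read_bed_genes(path) -> list[GeneInterval]:
    """Read gene intervals from BED (>= 3 columns; name col 4, strand col 6)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"gene{len(genes)}"
            strand = parts[5] if len(parts) > 5 else "+"
            genes.append(GeneInterval(chrom, start, end, strand, name))
    return genes


def write_bed_genes(genes: list[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Concatenated transcriptome

def build_concatenated_transcriptome(
    genome: dict[str, str], genes: list[GeneInterval]
) -> ConcatenatedTranscriptome:
    """Concatenate gene sequences in input order, coding-strand oriented.

    Minus-strand genes are reverse-complemented so that every position reads
    5'->3' along the direction of transcription.  N bases are kept in the
    sequence (code 4) and masked by downstream energy/PWM scoring.
    """
    parts: list[str] = []
    boundaries = [0]
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.name!r}: chromosome {g.chrom!r} not in genome")
        chrom_seq = genome[g.chrom]
        if g.end > len(chrom_seq):
            raise ValueError(
                f"gene {g.name!r}: interval [{g.start},{g.end}) exceeds "
                f"chromosome {g.chrom!r} length {len(chrom_seq)}"
            )
        seq = chrom_seq[g.start : g.end]
        if g.strand == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
        boundaries.append(boundaries[-1] + len(seq))
    sequence = "".join(parts)
    n = len(sequence)
    gene_id = np.zeros(n, dtype=np.int32)
    for i in range(1, len(genes)):
        gene_id[boundaries[i] : boundaries[i + 1]] = i
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in BASE_CODES.items():
        lut[ord(b)] = c
    codes = lut[codes]
    n_amb = int(np.sum(codes == 4))
    if n_amb:
        logger.info("transcriptome contains %d N positions (masked in scoring)", n_amb)
    return ConcatenatedTranscriptome(
        sequence=sequence,
        genes=list(genes),
        boundaries=np.asarray(boundaries, dtype=np.int64),
        gene_id=gene_id,
        codes=codes,
    )


# ---------------------------------------------------------------------------
# bedGraph coverage

def read_bedgraph(path, transcriptome: ConcatenatedTranscriptome, strand_of_file: str,
                  strain: str = "other") -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Only genes on ``strand_of_file`` receive counts; for minus-strand genes the
    genomic interval is mirrored into transcript orientation.  Positions that
    fall outside every same-strand gene are dropped (tally logged).  A position
    covered twice with conflicting values is an error.
    """
    if strand_of_file not in "+-":
        raise ValueError("strand_of_file must be '+' or '-'")
    counts = np.zeros(len(transcriptome), dtype=np.int64)
    assigned = np.zeros(len(transcriptome), dtype=bool)
    # per chromosome: same-strand genes sorted by genomic start
    by_chrom: dict[str, list[tuple[int, int, int, str]]] = {}
    for g, gene in enumerate(transcriptome.genes):
        if gene.strand == strand_of_file:
            by_chrom.setdefault(gene.chrom, []).append(
                (gene.start, gene.end, int(transcriptome.boundaries[g]), gene.strand)
            )
    for lst in by_chrom.values():
        lst.sort()

    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end {end} <= start {start}")
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative value {value}")
            ivalue = int(round(value))
            placed = 0
            for gstart, gend, boundary, strand in by_chrom.get(chrom, ()):
                lo, hi = max(start, gstart), min(end, gend)
                if lo >= hi:
                    continue
                if strand == "+":
                    sl = slice(boundary + lo - gstart, boundary + hi - gstart)
                    idx = np.arange(sl.start, sl.stop)
                else:
                    # genomic [lo,hi) maps to transcript offsets gend-hi .. gend-1-lo
                    idx = boundary + (gend - 1 - np.arange(lo, hi))
                conflict = assigned[idx] & (counts[idx] != ivalue)
                if np.any(conflict):
                    raise ValueError(
                        f"{path}:{ln}: overlapping bedGraph intervals with conflicting values"
                    )
                counts[idx] = ivalue
                assigned[idx] = True
                placed += hi - lo
            dropped += (end - start) - placed
    if dropped:
        logger.info("%s: %d bedGraph positions fell outside %s-strand genes and were dropped",
                    path, dropped, strand_of_file)
    return CoverageTrack(counts=counts, strain=strain)


def write_bedgraph(track: CoverageTrack, transcriptome: ConcatenatedTranscriptome,
                   strand: str, path) -> None:
    """Write the counts of genes on ``strand`` back to genomic bedGraph.

    Zero-count positions are omitted, matching sparse NET-seq convention.
    """
    with open(path, "w") as fh:
        for g, gene in enumerate(transcriptome.genes):
            if gene.strand != strand:
                continue
            lo, hi = int(transcriptome.boundaries[g]), int(transcriptome.boundaries[g + 1])
            vals = track.counts[lo:hi]
            # genomic coordinate of each transcript offset
            if gene.strand == "+":
                gpos = np.arange(gene.start, gene.end)
            else:
                gpos = np.arange(gene.end - 1, gene.start - 1, -1)
            order = np.argsort(gpos)
            gpos, vals = gpos[order], vals[order]
            nz = vals != 0
            for p, v in zip(gpos[nz], vals[nz]):
                fh.write(f"{gene.chrom}\t{p}\t{p + 1}\t{v}\n")


# ---------------------------------------------------------------------------
# Nucleosome centers

def read_nucleosome_table(path, one_based: bool = True) -> dict[str, np.ndarray]:
    """Read a TSV of nucleosome centers into ``{chrom: sorted unique 0-based centers}``.

    Default dialect is Brogaard-style 1-based positions; pass
    ``one_based=False`` for 0-based input.
    """
    centers: dict[str, list[int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected chrom<TAB>position")
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparseable position {parts[1]!r}") from exc
            centers.setdefault(parts[0], []).append(pos - 1 if one_based else pos)
    return {c: np.unique(np.asarray(v, dtype=np.int64)) for c, v in centers.items()}


def write_nucleosome_table(centers: dict[str, np.ndarray], path, one_based: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in centers:
            for p in centers[chrom]:
                fh.write(f"{chrom}\t{int(p) + (1 if one_based else 0)}\n")
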