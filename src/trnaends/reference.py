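"""Reference locus loading and alignment-window construction.

The analysis targets a single tRNA gene (for *B. subtilis* tRNA-Cys: 71
encoded nucleotides, CCA not genomically encoded) embedded in its genomic
context. Reads are aligned not to the bare gene but to a *window* -- the
gene in gene-sense orientation plus configurable flanks -- so that
precursor reads retaining genomically encoded leader/trailer nucleotides
remain fully alignable and distinguishable from post-transcriptionally
tailed species.

Coordinate conventions
----------------------
* BED input is half-open 0-based (standard BED).
* Internal gene coordinates are 1-based inclusive: position 1 is the first
  encoded gene base, ``gene_length`` (71 for tRNA-Cys) the last. The CCA
  end is never genomic.
* Window coordinates are 0-based Python indices into ``window_seq``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneLocus",
    "ReferenceWindow",
    "LocusError",
    "ReferenceMismatchError",
    "load_locus",
    "build_window",
    "read_fasta_dict",
]

DNA_ALPHABET = frozenset("ACGT")


class LocusError(ValueError):
    """Malformed locus descriptor (bad interval, strand or field count)."""


class ReferenceMismatchError(ValueError):
    """Locus refers to a chromosome absent from the reference FASTA."""


@dataclass(frozen=True)
class GeneLocus:
    """A single-copy tRNA gene locus, 1-based inclusive coordinates."""

    chrom_id: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: str = "tRNA"
    encodes_cca: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise LocusError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise LocusError(
                f"invalid interval [{self.start}, {self.end}] (1-based inclusive)"
            )

    @property
    def gene_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReferenceWindow:
    """Gene-sense alignment window: left flank + gene body + right flank.

    ``gene_offset`` is the 0-based index of gene position 1 within
    ``window_seq``; it always equals ``left_flank_len``.
    """

    window_seq: str
    left_flank_len: int
    right_flank_len: int
    gene_length: int
    locus: Union[GeneLocus, None] = None

    def __post_init__(self) -> None:
        expected = self.left_flank_len + self.gene_length + self.right_flank_len
        if len(self.window_seq) != expected:
            raise ValueError(
                f"window length {len(self.window_seq)} != flanks+gene {expected}"
            )
        bad = set(self.window_seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"window contains non-ACGT characters: {sorted(bad)}")

    @property
    def gene_offset(self) -> int:
        return self.left_flank_len

    @property
    def gene_seq(self) -> str:
        return self.window_seq[self.gene_offset : self.gene_offset + self.gene_length]

    @property
    def upstream_flank(self) -> str:
        return self.window_seq[: self.left_flank_len]

    @property
    def downstream_flank(self) -> str:
        return self.window_seq[self.gene_offset + self.gene_length :]

    def gene_to_window(self, gene_pos: int) -> int:
        """Map a 1-based gene position to a 0-based window index."""
        if not 1 <= gene_pos <= self.gene_length:
            raise IndexError(f"gene position {gene_pos} outside 1..{self.gene_length}")
        return self.gene_offset + gene_pos - 1

    def window_to_gene(self, window_idx: int) -> Union[int, None]:
        """Map a 0-based window index to a 1-based gene position.

        Returns None for flank positions.
        """
        if not 0 <= window_idx < len(self.window_seq):
            raise IndexError(f"window index {window_idx} out of range")
        pos = window_idx - self.gene_offset + 1
        return pos if 1 <= pos <= self.gene_length else None

    def to_fasta(self, path: Union[str, Path], name: str = "window") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n{self.window_seq}\n")


def _open_maybe_gzip(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta_dict(path: Union[str, Path]) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {id: sequence}."""
    with _open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def parse_bed6(line: str) -> GeneLocus:
    """Parse one BED line (>= 4 columns used: chrom, start, end, name[, score, strand]).

    BED is half-open 0-based; the returned locus is 1-based inclusive.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        fields = line.split()
    if len(fields) < 3:
        raise LocusError(f"BED line has fewer than 3 columns: {line!r}")
    chrom = fields[0]
    try:
        bed_start, bed_end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise LocusError(f"non-integer BED coordinates in {line!r}") from exc
    if bed_end <= bed_start:
        raise LocusError(f"zero/negative BED interval [{bed_start}, {bed_end})")
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else "tRNA"
    strand = fields[5] if len(fields) > 5 else "+"
    return GeneLocus(chrom_id=chrom, strand=strand, start=bed_start + 1, end=bed_end, name=name)


def load_locus(
    reference_fasta: Union[str, Path],
    locus_bed: Union[str, Path],
    expected_gene_length: Union[int, None] = None,
) -> GeneLocus:
    """Load and validate the gene locus against the reference FASTA.

    Parameters
    ----------
    reference_fasta : path
        Multi-record FASTA containing the chromosome named in the BED file.
    locus_bed : path
        BED file whose first non-comment record describes the gene.
    expected_gene_length : int, optional
        If given, the interval length must match (71 for tRNA-Cys).
    """
    seqs = read_fasta_dict(reference_fasta)
    locus = None
    with _open_maybe_gzip(locus_bed) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                locus = parse_bed6(line)
                break
    if locus is None:
        raise LocusError(f"no locus record found in {locus_bed}")
    if locus.chrom_id not in seqs:
        raise ReferenceMismatchError(
            f"chromosome {locus.chrom_id!r} not present in {reference_fasta}"
        )
    if locus.end > len(seqs[locus.chrom_id]):
        raise LocusError(
            f"locus end {locus.end} beyond chromosome length {len(seqs[locus.chrom_id])}"
        )
    if expected_gene_length is not None and locus.gene_length != expected_gene_length:
        raise LocusError(
            f"locus length {locus.gene_length} != expected {expected_gene_length}"
        )
    return locus


def build_window(genome_seq: str, locus: GeneLocus, flank: int = 50) -> ReferenceWindow:
    """Extract the gene plus up to ``flank`` nt of genomic context per side.

    Flanks are truncated at the chromosome ends. For minus-strand loci the
    window is reverse-complemented so that it reads in gene sense, and the
    flank that is genomically downstream of the gene's 3' end appears to
    the right of the gene body.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    genome_seq = genome_seq.upper()
    g0, g1 = locus.start - 1, locus.end  # 0-based half-open gene interval
    lo = max(0, g0 - flank)
    hi = min(len(genome_seq), g1 + flank)
    left = g0 - lo
    right = hi - g1
    seq = genome_seq[lo:hi]
    if locus.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        left, right = right, left
    return ReferenceWindow(
        window_seq=seq,
        left_flank_len=left,
        right_flank_len=right,
        gene_length=locus.gene_length,
        locus=locus,
    )
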