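"""Read streaming, 3' adapter trimming and basic quality filtering.

Small-RNA libraries read through the insert into the sequencing adapter, so
the 3' adapter must be trimmed before alignment. Trimming here is
cutadapt-style: the longest read suffix matching a prefix of the adapter
within a mismatch budget is removed. Reads containing ambiguous bases are
discarded entirely, and short leftovers (shorter than the minimum insert
worth classifying) are dropped; every drop is recorded with a reason so a
run log can account for all input reads.

No quality-score trimming is performed: only adapter removal and ambiguity
filtering.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

__all__ = ["Read", "ReadParseError", "read_sequences", "trim_adapter", "filter_read"]


class ReadParseError(ValueError):
    """A FASTQ/FASTA record could not be parsed; names the record index."""


@dataclass
class Read:
    read_id: str
    seq: str
    qual: Union[str, None] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ReadParseError(
                f"read {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_maybe_gzip(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    # fall back to first character
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_sequences(path: Union[str, Path]) -> Iterator[Read]:
    """Stream reads from FASTQ or FASTA (gzip transparent), order preserved."""
    path = Path(path)
    fmt = _sniff_format(path)
    index = 0
    with _open_maybe_gzip(path) as fh:
        try:
            if fmt == "fastq":
                # QualityIO tuple parser: cheap and validates seq/qual lengths
                for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
                    yield Read(title.split()[0], seq.upper(), qual)
                    index += 1
            else:
                for rec in SeqIO.parse(fh, "fasta"):
                    yield Read(rec.id, str(rec.seq).upper())
                    index += 1
        except ValueError as exc:
            raise ReadParseError(f"record {index} in {path}: {exc}") from exc


def trim_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> Read:
    """Remove a 3' adapter from the read.

    Scans for the leftmost read position i such that ``read.seq[i:]``
    matches ``adapter[:len(read)-i]`` with at most
    ``floor(max_error_rate * overlap)`` mismatches and overlap >=
    ``min_overlap`` (leftmost start = longest suffix removed). Overhang
    beyond the adapter length is not allowed. Returns the read unchanged if
    no qualifying match exists; may return a zero-length read when the read
    is pure adapter.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty when trimming is enabled")
    adapter = adapter.upper()
    seq = read.seq
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = n - i
        if overlap > len(adapter):
            continue
        allowed = int(max_error_rate * overlap)
        mism = 0
        for a, b in zip(seq[i:], adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            qual = read.qual[:i] if read.qual is not None else None
            return Read(read.read_id, seq[:i], qual, dict(read.meta))
    return read


def filter_read(read: Read, min_len: int = 15) -> tuple[bool, Union[str, None]]:
    """Keep/drop decision after trimming.

    Returns ``(True, None)`` to keep, or ``(False, reason)`` with reason in
    {"ambiguous", "too_short"}. Reads with any base outside {A,C,G,T} are
    dropped whole rather than N-trimmed.
    """
    if set(read.seq) - DNA_ALPHABET:
        return False, "ambiguous"
    if len(read.seq) < min_len:
        return False, "too_short"
    return True, None
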