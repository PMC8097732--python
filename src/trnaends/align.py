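"""Local alignment of reads to the reference window, with mapping filters.

Reads are aligned with affine-gap Smith-Waterman (Gotoh) against the small
gene-plus-flanks window, in both orientations. An alignment is accepted
only if it passes the study's mapping filters: length fraction >= 0.8
(aligned read bases / read length), similarity fraction >= 0.8 (identical
columns / alignment columns, gap columns included), at most 2 mismatches
and at most 3 indel *events* per read. Soft-clipped end segments are kept
verbatim -- they carry the post-transcriptional tail signal the classifier
needs -- and are never rescued by loosening thresholds.

The dynamic-programming fill is JIT-compiled with numba when available and
falls back to the identical pure-Python code otherwise.

Tie-breaking is deterministic: among equal-scoring end cells the smallest
window index, then the smallest read index, wins; traceback prefers
aligned columns over gaps and closes gaps as early as possible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .reads import Read
from .reference import ReferenceWindow

__all__ = [
    "ScoringScheme",
    "FilterThresholds",
    "MappedRead",
    "MapResult",
    "smith_waterman",
    "passes_filters",
    "map_read",
    "reverse_complement",
    "write_sam",
]

_NEG = -(10**7)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine scoring; a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class FilterThresholds:
    min_length_fraction: float = 0.8
    min_similarity_fraction: float = 0.8
    max_mismatches: int = 2
    max_indels: int = 3  # gap *events*, not gapped bases

    def __post_init__(self) -> None:
        for f in (self.min_length_fraction, self.min_similarity_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.max_mismatches < 0 or self.max_indels < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class MappedRead:
    """A filtered local alignment of one read against the window.

    ``ops`` is the per-column operation string over {=, X, I, D} in window
    order ('I' consumes a read base only, 'D' a window base only).
    ``window_start``/``window_end`` are 0-based, end exclusive. ``read_seq``
    is the read in the orientation that was aligned.
    """

    read_id: str
    read_seq: str
    window_start: int
    window_end: int
    ops: str
    score: int
    left_clip: str
    right_clip: str
    orientation: str = "sense"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_read = self.n_match + self.n_mismatch + self.n_ins_bases
        total = n_read + len(self.left_clip) + len(self.right_clip)
        if total != len(self.read_seq):
            raise ValueError(
                f"{self.read_id}: alignment consumes {total} read bases, "
                f"read has {len(self.read_seq)}"
            )
        n_win = self.n_match + self.n_mismatch + self.n_del_bases
        if self.window_end - self.window_start != n_win:
            raise ValueError(f"{self.read_id}: ops inconsistent with window interval")

    @property
    def n_match(self) -> int:
        return self.ops.count("=")

    @property
    def n_mismatch(self) -> int:
        return self.ops.count("X")

    @property
    def n_ins_bases(self) -> int:
        return self.ops.count("I")

    @property
    def n_del_bases(self) -> int:
        return self.ops.count("D")

    @property
    def n_columns(self) -> int:
        return len(self.ops)

    @property
    def aligned_read_bases(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins_bases

    @property
    def gap_events(self) -> int:
        return sum(1 for op, _ in itertools.groupby(self.ops) if op in "ID")

    @property
    def cigar(self) -> str:
        """CIGAR with soft clips and distinguished =/X columns."""
        parts = []
        if self.left_clip:
            parts.append(f"{len(self.left_clip)}S")
        for op, grp in itertools.groupby(self.ops):
            parts.append(f"{sum(1 for _ in grp)}{op}")
        if self.right_clip:
            parts.append(f"{len(self.right_clip)}S")
        return "".join(parts)


@dataclass(frozen=True)
class MapResult:
    """Outcome of mapping one read: mapped / unmapped / antisense."""

    status: str  # "mapped" | "unmapped" | "antisense"
    mapped: Optional[MappedRead] = None
    reason: Optional[str] = None


def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, H, E, F):
    n = a.shape[0]
    m = b.shape[0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            if a[i - 1] == b[j - 1]:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _gotoh_fill_jit = njit(cache=False)(_gotoh_fill)
except ImportError:  # pragma: no cover
    _gotoh_fill_jit = _gotoh_fill


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def smith_waterman(
    read_seq: str,
    window_seq: str,
    scoring: ScoringScheme = ScoringScheme(),
    read_id: str = "",
) -> Optional[MappedRead]:
    """Best-scoring local alignment of ``read_seq`` against ``window_seq``.

    Returns None when no alignment scores above zero (unalignable read).
    Non-ACGT characters never match anything.
    """
    if not read_seq or not window_seq:
        raise ValueError("sequences must be non-empty")
    a = _encode(read_seq)
    b = _encode(window_seq)
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    _gotoh_fill_jit(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, H, E, F
    )
    best = int(H.max())
    if best <= 0:
        return None
    # end cell: among maxima, smallest window index j, then smallest read index i
    flat = int(np.argmax(H.T))
    j = flat // (n + 1)
    i = flat % (n + 1)

    ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops.append("=" if a[i - 1] == b[j - 1] else "X")
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")
        elif state == "E":  # gap consuming window base (D)
            ops.append("D")
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                state = "H"
            j -= 1
        else:  # state == "F": gap consuming read base (I)
            ops.append("I")
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                state = "H"
            i -= 1
    ops.reverse()
    read_start, win_start = i, j
    read_end = read_start + sum(1 for o in ops if o in "=XI")
    win_end = win_start + sum(1 for o in ops if o in "=XD")
    return MappedRead(
        read_id=read_id,
        read_seq=read_seq,
        window_start=win_start,
        window_end=win_end,
        ops="".join(ops),
        score=best,
        left_clip=read_seq[:read_start],
        right_clip=read_seq[read_end:],
    )


def passes_filters(
    m: MappedRead, read_len: int, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool, Optional[str]]:
    """Apply the mapping filters; returns (ok, failure_reason)."""
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if m.aligned_read_bases / read_len < thresholds.min_length_fraction:
        return False, "length_fraction"
    if m.n_match / m.n_columns < thresholds.min_similarity_fraction:
        return False, "similarity_fraction"
    if m.n_mismatch > thresholds.max_mismatches:
        return False, "mismatches"
    if m.gap_events > thresholds.max_indels:
        return False, "indels"
    return True, None


def map_read(
    read: Read,
    window: ReferenceWindow,
    scoring: ScoringScheme = ScoringScheme(),
    thresholds: FilterThresholds = FilterThresholds(),
) -> MapResult:
    """Align a read in both orientations and keep the better passing hit.

    Antisense survivors are reported with status "antisense" so the caller
    can exclude them from maturation-state classification.
    """
    n = len(read.seq)
    sense = smith_waterman(read.seq, window.window_seq, scoring, read.read_id)
    anti = smith_waterman(
        reverse_complement(read.seq), window.window_seq, scoring, read.read_id
    )
    candidates = []
    fail_reason = "no_alignment"
    for aln, orient in ((sense, "sense"), (anti, "antisense")):
        if aln is None:
            continue
        ok, reason = passes_filters(aln, n, thresholds)
        if ok:
            candidates.append(replace(aln, orientation=orient, meta=dict(read.meta)))
        elif orient == "sense":
            fail_reason = reason
    if not candidates:
        return MapResult("unmapped", None, fail_reason)
    # sense wins ties
    best = max(candidates, key=lambda c: (c.score, c.orientation == "sense"))
    status = "mapped" if best.orientation == "sense" else "antisense"
    return MapResult(status, best, None)


def write_sam(
    mapped: list[MappedRead],
    window: ReferenceWindow,
    path,
    window_name: str = "window",
) -> None:
    """Export mapped reads as SAM against the window as reference."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": window_name, "LN": len(window.window_seq)}],
        "PG": [{"ID": "trnaends", "PN": "trnaends"}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mapped:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = m.read_id
            seg.query_sequence = m.read_seq
            seg.flag = 16 if m.orientation == "antisense" else 0
            seg.reference_id = 0
            seg.reference_start = m.window_start
            seg.mapping_quality = 60
            seg.cigarstring = m.cigar
            seg.set_tag("AS", m.score)
            seg.set_tag("NM", m.n_mismatch + m.n_ins_bases + m.n_del_bases)
            out.write(seg)
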