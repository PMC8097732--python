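"""Per-read 3'/5' end annotation and maturation-category assignment.

Each sense-mapped read is decomposed into the gene interval it covers plus
its unexplained end segments. Extra 3' bases are split into a *genomic*
prefix -- bases that continue the downstream genomic flank contiguously,
the signature of an unprocessed precursor trailer -- and the residual
*tail*, which must then be post-transcriptional (CCA-adding enzyme products
or aberrant additions). The 5' side is treated symmetrically for leaders.

Categories (for a gene of 71 encoded nt, CCA not genomic):

I     precursor: >= 1 genomically encoded base beyond either gene end
II    immature: exactly positions 1..71, no tail
III   mature: 1..71 + CCA
IV    immature: 1..71 + CC
V     3'-tRF (starts at >= 2, ends at 71) + CCA
VI    3'-tRF + CC
VII   5'-tRF (1..e, e < 71) or internal fragment; also tail-less or
      odd-tailed leftovers (flagged)
VIII  full-length with an incorrect tail (anything but "", CC, CCA)
IX    3'-tRF with an incorrect tail
UNCLASSIFIED  covers no gene position (flank-only read)

The decision order is a strict precedence: genomic extension (I) trumps
everything, then full-length tails (II/III/IV/VIII), then 3'-tRF tails
(V/VI/IX), then the fragment bucket (VII).

Tails are matched verbatim: a sequencing error inside a CCA tail lands the
read in VIII/IX. This is a known inflation source for the incorrect-tail
categories at high error rates; the rule is kept because error-tolerant
tail matching would require an error model the data cannot pin down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .align import MappedRead
from .reference import ReferenceWindow

__all__ = [
    "Category",
    "EndAnnotation",
    "ClassifiedRead",
    "annotate_ends",
    "classify",
    "classify_read",
    "CLASSIFIED_CATEGORIES",
]


class Category(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # plain value in tables
        return self.value


CLASSIFIED_CATEGORIES: tuple[Category, ...] = tuple(
    c for c in Category if c is not Category.UNCLASSIFIED
)


@dataclass
class EndAnnotation:
    """Decomposition of a mapped read around the gene body.

    ``gene_start``/``gene_end`` are 1-based encoded gene positions (<= gene
    length; the CCA is never genomic). ``five_extra``/``three_extra`` are
    the read bases before/after the covered gene interval;
    ``five_genomic_len``/``three_genomic_len`` how many of them continue
    the genomic flank contiguously from the gene boundary outward. The
    residual ``tail = three_extra[three_genomic_len:]`` is the inferred
    post-transcriptional addition.
    """

    gene_start: int
    gene_end: int
    gene_length: int
    five_extra: str
    three_extra: str
    five_genomic_len: int
    three_genomic_len: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.gene_start <= self.gene_end <= self.gene_length:
            raise ValueError(
                f"gene interval [{self.gene_start}, {self.gene_end}] invalid "
                f"for gene length {self.gene_length}"
            )
        if self.five_genomic_len > len(self.five_extra):
            raise ValueError("five_genomic_len exceeds five_extra")
        if self.three_genomic_len > len(self.three_extra):
            raise ValueError("three_genomic_len exceeds three_extra")

    @property
    def tail(self) -> str:
        return self.three_extra[self.three_genomic_len :]

    @property
    def missing_3p(self) -> int:
        """n in the 5'-tRF definition: encoded bases absent from the 3' end."""
        return self.gene_length - self.gene_end

    @property
    def is_full_length(self) -> bool:
        return self.gene_start == 1 and self.gene_end == self.gene_length


def _columns(m: MappedRead) -> list[tuple[str, Optional[int], Optional[int]]]:
    """Expand ops into (op, read_index, window_index) events."""
    events = []
    r = len(m.left_clip)
    w = m.window_start
    for op in m.ops:
        if op in "=X":
            events.append((op, r, w))
            r += 1
            w += 1
        elif op == "I":
            events.append((op, r, None))
            r += 1
        else:  # D
            events.append((op, None, w))
            w += 1
    return events


def annotate_ends(m: MappedRead, window: ReferenceWindow) -> Optional[EndAnnotation]:
    """Annotate gene coverage and end extensions; None for flank-only reads.

    Bases *aligned* within flank regions count toward the genomic extension
    lengths (matches and mismatches alike: a precursor trailer with a
    sequencing error is still a trailer); soft-clipped bases extend a
    genomic run only by exact, contiguous comparison against the flank
    sequence. An insertion breaks genomic contiguity.
    """
    if m.orientation != "sense":
        raise ValueError("only sense-oriented reads can be end-annotated")
    off = window.gene_offset
    glen = window.gene_length
    gene_hi = off + glen  # first window index past the gene
    events = _columns(m)
    gene_cols = [
        k
        for k, (op, r, w) in enumerate(events)
        if op in "=X" and w is not None and off <= w < gene_hi
    ]
    if not gene_cols:
        return None
    k0, k1 = gene_cols[0], gene_cols[-1]
    gene_start = events[k0][2] - off + 1
    gene_end = events[k1][2] - off + 1
    r_first = events[k0][1]
    r_last = events[k1][1]
    seq = m.read_seq
    five_extra = seq[:r_first]
    three_extra = seq[r_last + 1 :]

    # 5' genomic run: walk outward (leftward) from the first gene column
    five_gen = 0
    interrupted = False
    leftmost_w = events[k0][2]
    for op, r, w in reversed(events[:k0]):
        if op in "=X" and w is not None and w < off:
            five_gen += 1
            leftmost_w = w
        elif op == "D":
            leftmost_w = w
        else:  # insertion (or aligned gene column cannot occur left of k0)
            interrupted = True
            break
    if not interrupted and m.left_clip:
        w = leftmost_w - 1
        for base in reversed(m.left_clip):
            if w < 0 or w >= off or window.window_seq[w] != base:
                break
            five_gen += 1
            w -= 1

    # 3' genomic run: walk outward (rightward) from the last gene column
    three_gen = 0
    interrupted = False
    rightmost_w = events[k1][2]
    for op, r, w in events[k1 + 1 :]:
        if op in "=X" and w is not None and w >= gene_hi:
            three_gen += 1
            rightmost_w = w
        elif op == "D":
            rightmost_w = w
        else:
            interrupted = True
            break
    if not interrupted and m.right_clip:
        w = rightmost_w + 1
        for base in m.right_clip:
            if w >= len(window.window_seq) or w < gene_hi or window.window_seq[w] != base:
                break
            three_gen += 1
            w += 1

    flags = []
    if three_extra and gene_end == glen and window.downstream_flank[:1] == "C":
        # a genomic trailer starting with C is indistinguishable from the
        # first base of a CC/CCA tail; flag so downstream users can audit
        flags.append("flank_c_ambiguity")
    return EndAnnotation(
        gene_start=gene_start,
        gene_end=gene_end,
        gene_length=glen,
        five_extra=five_extra,
        three_extra=three_extra,
        five_genomic_len=five_gen,
        three_genomic_len=three_gen,
        flags=flags,
    )


def classify(a: EndAnnotation) -> tuple[Category, list[str]]:
    """Assign a category by strict precedence; total on valid annotations.

    Returns the label plus audit flags for reads the original category
    definitions do not place explicitly (single-C tails, tail-less 3'-tRFs
    ending at the last encoded position, tails on truncated reads).
    """
    flags = list(a.flags)
    if a.five_genomic_len >= 1 or a.three_genomic_len >= 1:
        return Category.I, flags
    tail = a.tail
    if a.is_full_length:
        if tail == "":
            return Category.II, flags
        if tail == "CCA":
            return Category.III, flags
        if tail == "CC":
            return Category.IV, flags
        if tail == "C":
            flags.append("single_c_tail")
        return Category.VIII, flags
    if a.gene_start >= 2 and a.gene_end == a.gene_length and tail != "":
        if tail == "CCA":
            return Category.V, flags
        if tail == "CC":
            return Category.VI, flags
        if tail == "C":
            flags.append("single_c_tail")
        return Category.IX, flags
    if a.gene_start >= 2 and a.gene_end == a.gene_length and tail == "":
        flags.append("three_trf_no_tail")
    if a.gene_end < a.gene_length and tail != "":
        flags.append("tail_on_truncated_3end")
    return Category.VII, flags


@dataclass
class ClassifiedRead:
    read_id: str
    category: Category
    gene_start: Optional[int] = None
    gene_end: Optional[int] = None
    tail: str = ""
    five_genomic_len: int = 0
    three_genomic_len: int = 0
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "read_id": self.read_id,
            "gene_start": "" if self.gene_start is None else self.gene_start,
            "gene_end": "" if self.gene_end is None else self.gene_end,
            "tail": self.tail,
            "genomic_len5": self.five_genomic_len,
            "genomic_len3": self.three_genomic_len,
            "category": self.category.value,
            "flags": ";".join(self.flags),
        }


def classify_read(m: MappedRead, window: ReferenceWindow) -> ClassifiedRead:
    """Annotate + classify one sense-mapped read (UNCLASSIFIED if flank-only)."""
    ann = annotate_ends(m, window)
    if ann is None:
        return ClassifiedRead(
            m.read_id, Category.UNCLASSIFIED, flags=["flank_only"], meta=dict(m.meta)
        )
    label, flags = classify(ann)
    return ClassifiedRead(
        read_id=m.read_id,
        category=label,
        gene_start=ann.gene_start,
        gene_end=ann.gene_end,
        tail=ann.tail,
        five_genomic_len=ann.five_genomic_len,
        three_genomic_len=ann.three_genomic_len,
        flags=flags,
        meta=dict(m.meta),
    )
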