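"""End annotation and category assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnaends.align import MappedRead, map_read, smith_waterman
from trnaends.classify import (
    Category,
    EndAnnotation,
    annotate_ends,
    classify,
    classify_read,
)
from trnaends.reads import Read


def _ann(gene_start, gene_end, tail, five_gen=0, three_gen=0, gene_length=71):
    """EndAnnotation with the given decomposition (extras built to match)."""
    return EndAnnotation(
        gene_start=gene_start,
        gene_end=gene_end,
        gene_length=gene_length,
        five_extra="G" * five_gen,
        three_extra="G" * three_gen + tail,
        five_genomic_len=five_gen,
        three_genomic_len=three_gen,
    )


@pytest.mark.parametrize(
    "ann, expected",
    [
        (_ann(1, 71, "CCA"), Category.III),
        (_ann(1, 71, ""), Category.II),
        (_ann(1, 71, "CC"), Category.IV),
        (_ann(10, 71, "CCA"), Category.V),
        (_ann(10, 71, "CC"), Category.VI),
        (_ann(1, 55, ""), Category.VII),
        (_ann(5, 68, ""), Category.VII),
        (_ann(1, 71, "CCACCA"), Category.VIII),
        (_ann(12, 71, "CCAAAAA"), Category.IX),
        (_ann(1, 71, "", five_gen=3), Category.I),
        (_ann(1, 71, "", three_gen=6), Category.I),
        (_ann(1, 71, "C"), Category.VIII),  # single-C tail, flagged
        (_ann(2, 71, ""), Category.VII),  # tail-less 3'-tRF, flagged
        (_ann(1, 71, "CCA", three_gen=1), Category.I),  # precedence
    ],
)
def test_category_assignment(ann, expected):
    label, _ = classify(ann)
    assert label is expected


def test_unplaced_species_are_flagged():
    label, flags = classify(_ann(1, 71, "C"))
    assert label is Category.VIII and "single_c_tail" in flags
    label, flags = classify(_ann(2, 71, ""))
    assert label is Category.VII and "three_trf_no_tail" in flags
    label, flags = classify(_ann(1, 70, "CCA"))
    assert label is Category.VII and "tail_on_truncated_3end" in flags


def test_five_trf_missing_length():
    ann = _ann(1, 55, "")
    assert ann.missing_3p == 16  # n = 71 - gene_end


@settings(derandomize=True, max_examples=300)
@given(
    gene_start=st.integers(1, 71),
    span=st.integers(0, 70),
    tail=st.text(alphabet="CA", max_size=6),
    five_gen=st.integers(0, 5),
    three_gen=st.integers(0, 5),
)
def test_classification_is_total_and_deterministic(gene_start, span, tail, five_gen, three_gen):
    gene_end = min(gene_start + span, 71)
    ann = _ann(gene_start, gene_end, tail, five_gen, three_gen)
    label1, _ = classify(ann)
    label2, _ = classify(ann)
    assert label1 is label2
    assert label1 in set(Category) - {Category.UNCLASSIFIED}


@settings(derandomize=True, max_examples=200)
@given(
    gene_start=st.integers(1, 71),
    span=st.integers(0, 70),
    tail=st.text(alphabet="CA", max_size=6),
)
def test_adding_genomic_trailer_always_yields_precursor(gene_start, span, tail):
    """Precedence: any genomic extension converts the label to I, never
    to some other new label."""
    gene_end = min(gene_start + span, 71)
    with_trailer = _ann(gene_start, gene_end, tail, three_gen=2)
    label, _ = classify(with_trailer)
    assert label is Category.I


# --- annotation from real alignments -------------------------------------


def test_tail_not_matching_flank_stays_tail(window):
    read = Read("r", window.gene_seq + "CCA")
    m = map_read(read, window).mapped
    ann = annotate_ends(m, window)
    assert (ann.gene_start, ann.gene_end) == (1, 71)
    assert ann.three_genomic_len == 0
    assert ann.tail == "CCA"


def test_aligned_trailer_counts_as_genomic(window):
    read = Read("r", window.gene_seq + window.downstream_flank[:6])
    m = map_read(read, window).mapped
    ann = annotate_ends(m, window)
    assert ann.three_genomic_len == 6
    assert ann.tail == ""
    assert classify(ann)[0] is Category.I


def test_aligned_leader_counts_as_genomic(window):
    read = Read("r", window.upstream_flank[-4:] + window.gene_seq)
    m = map_read(read, window).mapped
    ann = annotate_ends(m, window)
    assert ann.five_genomic_len == 4
    assert classify(ann)[0] is Category.I


def test_clipped_bases_extend_genomic_run_by_exact_match(window):
    """A soft-clipped 3' segment equal to the flank prefix is genomic.

    Built by hand (local alignment would normally absorb matching bases):
    right_clip "GT.." equals the start of the downstream flank.
    """
    off, glen = window.gene_offset, window.gene_length
    clip = window.downstream_flank[:2]
    m = MappedRead(
        read_id="r",
        read_seq=window.gene_seq + clip,
        window_start=off,
        window_end=off + glen,
        ops="=" * glen,
        score=2 * glen,
        left_clip="",
        right_clip=clip,
    )
    ann = annotate_ends(m, window)
    assert ann.three_genomic_len == 2
    assert ann.tail == ""
    assert classify(ann)[0] is Category.I


def test_clip_genomic_split_matches_bruteforce_enumeration(window):
    """three_genomic_len equals the naive longest-contiguous-prefix match
    of the clipped segment against the downstream flank, for every clip
    over {C, A, G, T} up to length 3."""
    import itertools

    off, glen = window.gene_offset, window.gene_length
    flank = window.downstream_flank
    for k in (1, 2, 3):
        for clip in map("".join, itertools.product("CAGT", repeat=k)):
            m = MappedRead(
                read_id="r",
                read_seq=window.gene_seq + clip,
                window_start=off,
                window_end=off + glen,
                ops="=" * glen,
                score=2 * glen,
                left_clip="",
                right_clip=clip,
            )
            ann = annotate_ends(m, window)
            expected = 0
            for a, b in zip(clip, flank):
                if a != b:
                    break
                expected += 1
            assert ann.three_genomic_len == expected, clip
            assert ann.tail == clip[expected:]


def test_flank_only_read_is_unclassified(window):
    read = Read("r", window.upstream_flank[10:35])
    res = map_read(read, window)
    assert res.status == "mapped"
    cr = classify_read(res.mapped, window)
    assert cr.category is Category.UNCLASSIFIED
    assert "flank_only" in cr.flags


def test_antisense_reads_are_rejected_from_annotation(window):
    from trnaends.align import reverse_complement

    m = map_read(Read("r", reverse_complement(window.gene_seq)), window).mapped
    with pytest.raises(ValueError):
        annotate_ends(m, window)
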