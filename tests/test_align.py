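"""Local alignment: oracle agreement, filters, orientation handling."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from trnaends.align import (
    FilterThresholds,
    MappedRead,
    ScoringScheme,
    map_read,
    passes_filters,
    reverse_complement,
    smith_waterman,
    write_sam,
)
from trnaends.reads import Read

DEFAULT = ScoringScheme()
ALT = ScoringScheme(match=3, mismatch=-2, gap_open=-4, gap_extend=-1)


def oracle_local_score(a: str, b: str, sc: ScoringScheme) -> int:
    """Independent oracle: top-down recursion over alignment continuations.

    From every start cell, recursively extends the alignment one operation
    at a time (substitution column, or a gap consuming one base of either
    sequence, with affine costs), allowing a stop at any point. Memoized on
    (position, gap state); shares no code or matrix structure with the
    implementation under test.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, state: str) -> int:
        best = 0  # stop here
        if i < n and j < m:
            s = sc.match if a[i] == b[j] else sc.mismatch
            best = max(best, s + extend(i + 1, j + 1, "M"))
        if j < m:
            cost = sc.gap_extend if state == "D" else sc.gap_open
            best = max(best, cost + extend(i, j + 1, "D"))
        if i < n:
            cost = sc.gap_extend if state == "I" else sc.gap_open
            best = max(best, cost + extend(i + 1, j, "I"))
        return best

    best = 0
    for i in range(n):
        for j in range(m):
            best = max(best, extend(i, j, "start"))
    return best


def exhaustive_local_score(a: str, b: str, sc: ScoringScheme) -> int:
    """Fully exhaustive enumeration of every operation path (tiny inputs)."""
    n, m = len(a), len(b)
    best = 0

    def rec(i, j, score, state):
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            s = sc.match if a[i] == b[j] else sc.mismatch
            rec(i + 1, j + 1, score + s, "M")
        if j < m:
            rec(i, j + 1, score + (sc.gap_extend if state == "D" else sc.gap_open), "D")
        if i < n:
            rec(i + 1, j, score + (sc.gap_extend if state == "I" else sc.gap_open), "I")

    for i in range(n):
        for j in range(m):
            rec(i, j, 0, "start")
    return best


def _random_pairs(rng, n_pairs, max_len):
    bases = list("ACGT")
    for _ in range(n_pairs):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        yield (
            "".join(rng.choice(bases, size=la)),
            "".join(rng.choice(bases, size=lb)),
        )


def test_oracle_matches_exhaustive_enumeration_on_tiny_pairs():
    """The memoized oracle itself agrees with brute-force path enumeration."""
    rng = np.random.default_rng(42)
    for a, b in _random_pairs(rng, 12, 4):
        for sc in (DEFAULT, ALT):
            assert oracle_local_score(a, b, sc) == exhaustive_local_score(a, b, sc)


@pytest.mark.parametrize("scoring", [DEFAULT, ALT], ids=["default", "alt"])
def test_smith_waterman_matches_oracle_on_random_pairs(scoring):
    rng = np.random.default_rng(123)
    checked = 0
    for a, b in _random_pairs(rng, 250, 8):
        expected = oracle_local_score(a, b, scoring)
        aln = smith_waterman(a, b, scoring)
        got = 0 if aln is None else aln.score
        assert got == expected, (a, b)
        checked += 1
    assert checked >= 200


def test_perfect_self_alignment():
    aln = smith_waterman("GATTACA", "GATTACA")
    assert aln.score == 7 * DEFAULT.match
    assert aln.ops == "=" * 7
    assert aln.left_clip == "" and aln.right_clip == ""


def test_unalignable_sequences_return_none():
    assert smith_waterman("AAAA", "TTTT") is None


def test_alignment_is_deterministic():
    rng = np.random.default_rng(9)
    for a, b in _random_pairs(rng, 20, 30):
        first = smith_waterman(a, b)
        second = smith_waterman(a, b)
        if first is None:
            assert second is None
            continue
        assert (first.ops, first.window_start, first.left_clip) == (
            second.ops,
            second.window_start,
            second.left_clip,
        )


def test_mapped_read_conserves_read_bases(window):
    """match + mismatch + inserted + clipped bases == read length."""
    rng = np.random.default_rng(3)
    win = window.window_seq
    for _ in range(30):
        start = int(rng.integers(0, len(win) - 40))
        seq = win[start : start + 35] + "CCA"
        aln = smith_waterman(seq, win)
        assert aln is not None
        total = (
            aln.n_match
            + aln.n_mismatch
            + aln.n_ins_bases
            + len(aln.left_clip)
            + len(aln.right_clip)
        )
        assert total == len(seq)


def _mk(ops, read_len, left=0, right=0):
    """Build a synthetic MappedRead with the given column string."""
    n_read = sum(1 for o in ops if o in "=XI")
    seq = "A" * (left + n_read + right)
    n_win = sum(1 for o in ops if o in "=XD")
    return MappedRead(
        read_id="r",
        read_seq=seq,
        window_start=10,
        window_end=10 + n_win,
        ops=ops,
        score=1,
        left_clip="A" * left,
        right_clip="A" * right,
    )


@pytest.mark.parametrize(
    "ops, left, right, read_len, expected",
    [
        ("=" * 23, 3, 4, 30, (False, "length_fraction")),  # 23/30 = 0.767
        ("=" * 27 + "X" * 3, 0, 0, 30, (False, "mismatches")),
        ("=" * 30, 0, 0, 30, (True, None)),
        ("=" * 10 + "X" * 10, 0, 0, 20, (False, "similarity_fraction")),
        ("=" * 26 + "D" + "=" * 2 + "D" + "=" + "D" + "=" + "D=", 0, 0, 31, (False, "indels")),
    ],
)
def test_mapping_filters(ops, left, right, read_len, expected):
    m = _mk(ops, read_len, left, right)
    assert passes_filters(m, read_len, FilterThresholds()) == expected


def test_indel_budget_counts_events_not_bases():
    # one 3-base deletion = a single event, passes; similarity 30/33 = 0.909
    m = _mk("=" * 15 + "DDD" + "=" * 15, 30)
    ok, reason = passes_filters(m, 30)
    assert ok, reason
    assert m.gap_events == 1 and m.n_del_bases == 3


def test_tightening_any_threshold_never_admits_more_reads(window):
    """Monotonicity of the filter set over a fixed simulated sample."""
    from trnaends.simulate import Mixture, fig1_proportions, simulate_sample

    mix = Mixture(proportions=fig1_proportions(), n_reads=300, error_rate=0.03)
    reads, _ = simulate_sample(window, mix, seed=21)
    alns = []
    for r in reads:
        a = smith_waterman(r.seq, window.window_seq)
        if a is not None:
            alns.append((a, len(r.seq)))

    def n_passing(t):
        return sum(1 for a, n in alns if passes_filters(a, n, t)[0])

    base = FilterThresholds()
    prev = None
    for lf in (0.5, 0.7, 0.8, 0.9, 1.0):
        cur = n_passing(FilterThresholds(min_length_fraction=lf))
        assert prev is None or cur <= prev
        prev = cur
    prev = None
    for sf in (0.5, 0.7, 0.8, 0.9, 1.0):
        cur = n_passing(FilterThresholds(min_similarity_fraction=sf))
        assert prev is None or cur <= prev
        prev = cur
    prev = None
    for mm in (5, 3, 2, 1, 0):
        cur = n_passing(FilterThresholds(max_mismatches=mm))
        assert prev is None or cur <= prev
        prev = cur
    prev = None
    for ind in (5, 3, 1, 0):
        cur = n_passing(FilterThresholds(max_indels=ind))
        assert prev is None or cur <= prev
        prev = cur
    assert n_passing(base) > 200  # fixture sample mostly mappable


def test_map_read_orientations(window):
    gene_cca = window.gene_seq + "CCA"
    res = map_read(Read("fwd", gene_cca), window)
    assert res.status == "mapped"
    assert res.mapped.right_clip == "CCA"
    assert res.mapped.orientation == "sense"

    res_rc = map_read(Read("rev", reverse_complement(gene_cca)), window)
    assert res_rc.status == "antisense"

    res_bad = map_read(Read("junk", "ACGT" * 8), window)
    # a random 32-mer has no 80%-similar full-length hit in a 191-nt window
    assert res_bad.status == "unmapped"


def test_sam_export_roundtrip(window, tmp_path):
    pysam = pytest.importorskip("pysam")
    reads = [
        Read("a", window.gene_seq + "CCA"),
        Read("b", window.gene_seq[9:]),
    ]
    mapped = [map_read(r, window).mapped for r in reads]
    path = tmp_path / "out.sam"
    write_sam(mapped, window, path)
    with pysam.AlignmentFile(str(path)) as fh:
        recs = list(fh)
    assert [r.query_name for r in recs] == ["a", "b"]
    assert recs[0].cigarstring.endswith("3S")
    assert recs[1].reference_start == mapped[1].window_start
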