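"""Ground-truth read simulation over a synthetic tRNA locus.

Every pipeline stage is testable without downloads: a random 71-nt gene is
embedded in random flanks, and labeled reads are drawn from a configurable
mixture of the nine maturation/fragmentation categories, with geometric
leader/trailer lengths for precursors, uniform fragment endpoints, a
repertoire of aberrant tails, and an iid per-base substitution error.

Two generator guarantees keep truth recovery exact at error rate zero:

* the first bases of the downstream flank are drawn from {G, T} only, so
  post-transcriptional tails (which are all over {C, A}) can never extend a
  local alignment into the flank, nor be mistaken for genomic trailer;
* every read is constructed to satisfy the default mapping filters (in
  particular, a fragment carrying an aberrant tail is at least four times
  the tail length, so the 0.8 length fraction holds by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .classify import Category
from .reference import GeneLocus, ReferenceWindow
from .study import load_study_runs

__all__ = [
    "Mixture",
    "TruthRecord",
    "fig1_proportions",
    "outgrowth_proportions",
    "generate_reference",
    "simulate_sample",
    "simulate_study",
    "write_fastq",
    "write_truth",
    "DEFAULT_TAIL_REPERTOIRE",
    "POLY_A_TAIL",
]

SIM_CATEGORIES = [c for c in Category if c is not Category.UNCLASSIFIED]

#: sentinel for "CCA followed by a poly(A) stretch of random length 1..6"
POLY_A_TAIL = "CCA+polyA"

DEFAULT_TAIL_REPERTOIRE: tuple[str, ...] = (
    "CCAC",
    "CCACA",
    "CCACCA",
    POLY_A_TAIL,
    "C",
    "CA",
)

# flank prefix kept free of C and A so tails are always soft-clipped
_SAFE_TRAILER_PREFIX = 12

_FIG1_RAW = {
    "I": 1.01,
    "II": 0.34,
    "III": 22.85,
    "IV": 9.47,
    "V": 23.19 / 2,
    "VI": 23.19 / 2,
    "VII": 30.46,
    "VIII": 7.0,
    "IX": 5.27,
}

_OUTGROWTH_RAW = {
    "I": 0.25,
    "II": 0.005,
    "III": 0.12,
    "IV": 0.02,
    "V": 0.04,
    "VI": 0.01,
    "VII": 0.45,
    "VIII": 0.08,
    "IX": 0.025,
}


def _normalize(props: dict[str, float]) -> dict[str, float]:
    total = sum(props.values())
    return {k: v / total for k, v in props.items()}


def fig1_proportions() -> dict[str, float]:
    """The dormant-spore category mixture, normalized to sum to 1.

    The published per-category percentages sum to 99.59, not 100 (rounding
    plus reads the figure does not place); the simulator needs a proper
    probability vector, so they are rescaled by 1/0.9959. The V/VI split is
    not printed separately and is taken as even.
    """
    return _normalize(dict(_FIG1_RAW))


def outgrowth_proportions() -> dict[str, float]:
    """Illustrative outgrowth mixture: precursor- and fragment-dominated.

    Qualitative shape only (precursors and 5'-tRFs up; CC-ended species and
    CCA-tailed fragments down, mature share moderate), for end-to-end runs.
    """
    return _normalize(dict(_OUTGROWTH_RAW))


@dataclass
class Mixture:
    """Generator configuration for one sample."""

    proportions: dict
    n_reads: int
    error_rate: float = 0.0
    leader_p: float = 0.3  # geometric parameter, support 0,1,2,...
    trailer_p: float = 0.3
    min_fragment_len: int = 15  # matches the read filter's min length
    tail_repertoire: tuple = DEFAULT_TAIL_REPERTOIRE
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        props = {
            (k.value if isinstance(k, Category) else str(k)): float(v)
            for k, v in self.proportions.items()
        }
        unknown = set(props) - {c.value for c in SIM_CATEGORIES}
        if unknown:
            raise ValueError(f"unknown categories in mixture: {sorted(unknown)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {sum(props.values())}, not 1")
        self.proportions = props
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for t in self.tail_repertoire:
            if t != POLY_A_TAIL and t in ("", "CC", "CCA"):
                raise ValueError(f"tail {t!r} is a correct-processing tail")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    category: str
    gene_start: int
    gene_end: int
    tail: str
    leader_len: int = 0
    trailer_len: int = 0
    n_errors: int = 0


def generate_reference(
    seed: int, gene_length: int = 71, flank: int = 60
) -> ReferenceWindow:
    """Random gene inside flanks, with the tail-disambiguation constraint.

    The first ``_SAFE_TRAILER_PREFIX`` bases of the downstream flank are
    drawn from {G, T}; all other positions are uniform over ACGT.
    """
    if flank < _SAFE_TRAILER_PREFIX:
        raise ValueError(f"flank must be >= {_SAFE_TRAILER_PREFIX}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    gt = np.array(list("GT"))
    left = "".join(rng.choice(bases, size=flank))
    gene = "".join(rng.choice(bases, size=gene_length))
    right_safe = "".join(rng.choice(gt, size=_SAFE_TRAILER_PREFIX))
    right_rest = "".join(rng.choice(bases, size=flank - _SAFE_TRAILER_PREFIX))
    window = left + gene + right_safe + right_rest
    locus = GeneLocus(
        chrom_id="synthetic_ref",
        strand="+",
        start=flank + 1,
        end=flank + gene_length,
        name="trn-synthetic",
    )
    return ReferenceWindow(
        window_seq=window,
        left_flank_len=flank,
        right_flank_len=flank,
        gene_length=gene_length,
        locus=locus,
    )


def write_reference(window: ReferenceWindow, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Export the synthetic chromosome (the window itself) as FASTA + BED."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "reference.fasta"
    bed = out_dir / "locus.bed"
    locus = window.locus
    chrom = locus.chrom_id if locus is not None else "synthetic_ref"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n{window.window_seq}\n")
    start0 = window.gene_offset  # BED half-open 0-based
    with open(bed, "w") as fh:
        name = locus.name if locus is not None else "tRNA"
        fh.write(
            f"{chrom}\t{start0}\t{start0 + window.gene_length}\t{name}\t.\t+\n"
        )
    return {"fasta": fasta, "bed": bed}


def _draw_tail(rng: np.random.Generator, repertoire: Sequence[str]) -> str:
    t = repertoire[int(rng.integers(0, len(repertoire)))]
    if t == POLY_A_TAIL:
        return "CCA" + "A" * int(rng.integers(1, 7))
    return t


def _geometric0(rng: np.random.Generator, p: float, cap: int) -> int:
    # geometric on {0, 1, 2, ...} truncated at the flank length
    return min(int(rng.geometric(p)) - 1, cap)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate == 0.0 or not seq:
        return seq, 0
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr), int(hits.size)


def simulate_sample(
    window: ReferenceWindow,
    mixture: Mixture,
    seed: Optional[int] = None,
    sample_id: str = "sample",
) -> tuple[list, list[TruthRecord]]:
    """Draw labeled reads from the mixture; returns (reads, truth records).

    Construction per category (gene positions 1-based, L = gene length):
    I   full gene plus a genomic leader and/or trailer (geometric lengths,
        at least one side non-empty, truncated at the flanks)
    II  gene 1..L              III  gene 1..L + CCA     IV  gene 1..L + CC
    V   gene s..L + CCA        VI   gene s..L + CC      (s uniform 2..L-15)
    VII gene 1..e (e uniform 15..L-1) or internal s..e (length >= 15, e<=L-1)
    VIII full gene + aberrant tail    IX  gene s..L + aberrant tail, with
        the fragment at least 4x the tail length so the read stays mappable
    then iid substitutions at ``error_rate``; constant quality 'I'.
    """
    from .reads import Read  # local import to avoid cycle at module load

    if seed is None:
        seed = mixture.seed
    if seed is None:
        raise ValueError("a seed is required (in the mixture or as an argument)")
    L = window.gene_length
    minf = mixture.min_fragment_len
    if minf > L:
        raise ValueError(f"min fragment length {minf} exceeds gene length {L}")
    rng = np.random.default_rng(seed)
    gene = window.gene_seq
    up = window.upstream_flank
    down = window.downstream_flank
    cats = [c.value for c in SIM_CATEGORIES]
    probs = np.array([mixture.proportions.get(c, 0.0) for c in cats])
    draws = rng.choice(len(cats), size=mixture.n_reads, p=probs)

    reads: list[Read] = []
    truth: list[TruthRecord] = []
    s_hi_trf = L - minf + 1  # largest 3'-tRF start keeping length >= minf
    for idx, ci in enumerate(draws):
        cat = cats[int(ci)]
        leader = trailer = 0
        gs, ge, tail = 1, L, ""
        if cat == "I":
            while leader == 0 and trailer == 0:
                leader = _geometric0(rng, mixture.leader_p, len(up))
                trailer = _geometric0(rng, mixture.trailer_p, len(down))
            seq = (up[len(up) - leader :] if leader else "") + gene
            seq += down[:trailer]
        elif cat == "II":
            seq = gene
        elif cat == "III":
            tail = "CCA"
            seq = gene + tail
        elif cat == "IV":
            tail = "CC"
            seq = gene + tail
        elif cat in ("V", "VI"):
            gs = int(rng.integers(2, s_hi_trf + 1))
            tail = "CCA" if cat == "V" else "CC"
            seq = gene[gs - 1 :] + tail
        elif cat == "VII":
            if rng.random() < 0.5:  # 5'-tRF
                ge = int(rng.integers(minf, L))
                seq = gene[:ge]
            else:  # internal fragment
                gs = int(rng.integers(2, L - minf - 1 + 1))
                ge = int(rng.integers(gs + minf - 1, L - 1 + 1))
                seq = gene[gs - 1 : ge]
        elif cat == "VIII":
            tail = _draw_tail(rng, mixture.tail_repertoire)
            seq = gene + tail
        else:  # IX
            tail = _draw_tail(rng, mixture.tail_repertoire)
            need = max(minf, 4 * len(tail))
            gs = int(rng.integers(2, L - need + 1 + 1))
            seq = gene[gs - 1 :] + tail
        seq, n_err = _apply_errors(rng, seq, mixture.error_rate)
        rid = f"{sample_id}_{idx:06d}"
        reads.append(
            Read(rid, seq, "I" * len(seq), {"sample": sample_id, "true_category": cat})
        )
        truth.append(
            TruthRecord(
                read_id=rid,
                category=cat,
                gene_start=gs,
                gene_end=ge,
                tail=tail,
                leader_len=leader,
                trailer_len=trailer,
                n_errors=n_err,
            )
        )
    return reads, truth


def write_fastq(reads, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual or 'I' * len(r.seq)}\n")


def write_truth(truth: Sequence[TruthRecord], path: Union[str, Path]) -> None:
    cols = (
        "read_id\ttrue_category\tgene_start\tgene_end\ttail\t"
        "leader_len\ttrailer_len\tn_errors\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.category}\t{t.gene_start}\t{t.gene_end}\t"
                f"{t.tail}\t{t.leader_len}\t{t.trailer_len}\t{t.n_errors}\n"
            )


@dataclass
class StudyConfig:
    """Layout for a full synthetic study mirroring the 14-run design."""

    seed: int
    error_rate: float = 0.0
    n_reads: Optional[dict] = None  # (condition, time, replicate) -> count
    mixtures: Optional[dict] = None  # (condition, time) -> proportions
    scale: float = 1.0  # multiplier on the default per-run read counts


def default_study_layout() -> list[tuple[str, str, int, int, int]]:
    """(sample_id, condition, time_min, replicate, n_reads) per default run.

    Read depths mirror the published per-run locus-mapped counts.
    """
    runs = load_study_runs()
    layout = []
    for _, row in runs.iterrows():
        cond, t, rep = row["condition"], int(row["time_min"]), int(row["replicate"])
        sid = ("T0" if cond == "dormant" else f"{cond}_T{t}") + f"_rep{rep}"
        layout.append((sid, cond, t, rep, int(row["mapped_reads"])))
    return layout


def simulate_study(
    config: StudyConfig, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Emit the full synthetic corpus: reference, 14 FASTQs, truth, sheet."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = generate_reference(config.seed)
    paths = write_reference(window, out_dir)
    mixtures = config.mixtures or {}
    sheet_rows = []
    sub_rng = np.random.default_rng(config.seed)
    for sid, cond, t, rep, n_default in default_study_layout():
        props = mixtures.get(
            (cond, t), fig1_proportions() if t == 0 else outgrowth_proportions()
        )
        n = n_default
        if config.n_reads and (cond, t, rep) in config.n_reads:
            n = int(config.n_reads[(cond, t, rep)])
        n = int(round(n * config.scale))
        mix = Mixture(proportions=props, n_reads=n, error_rate=config.error_rate)
        sample_seed = int(sub_rng.integers(0, 2**31 - 1))
        reads, truth = simulate_sample(window, mix, seed=sample_seed, sample_id=sid)
        fq = out_dir / f"{sid}.fastq"
        tr = out_dir / f"{sid}.truth.tsv"
        write_fastq(reads, fq)
        write_truth(truth, tr)
        sheet_rows.append((sid, cond, t, rep, fq.name, tr.name))
    sheet = out_dir / "sample_sheet.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tcondition\ttime_min\treplicate\tfastq\ttruth\n")
        for row in sheet_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths["sample_sheet"] = sheet
    return paths
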