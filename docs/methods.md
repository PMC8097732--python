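# Methods

## Model of the locus and read provenance

The package models a single-copy tRNA gene (the *B. subtilis* tRNA-Cys
case: 71 encoded nucleotides, 3′-CCA added enzymatically, the gene at the
distal end of the *rrnD* operon) and interprets every small-RNA read
mapping to it as a snapshot of one molecule's processing state. The
observable is the read's decomposition against a *reference window*: the
gene in gene-sense orientation with genomic flanks (default 50 nt per side,
configurable; flanks are what make precursor leaders/trailers alignable).
Internally the gene is addressed 1-based (position 1 = first encoded base,
71 = last; the CCA is never genomic), BED input is standard half-open
0-based, and minus-strand loci are reverse-complemented into gene sense at
window construction.

Assumptions inherited from this design:

- a single locus suffices (multi-mapping elsewhere in the genome is out of
  scope; the analysis is conditional on reads that align to this window);
- substitution-dominated sequencing error; no modeling of
  modification-induced reverse-transcriptase fall-off, which in real
  spore RNA inflates apparent 5′-truncation (category VII) — percentages on
  real data are therefore upper bounds for genuine fragments;
- 3′ tails are read verbatim: an error inside a CCA tail moves a read from
  III/V to VIII/IX. No error-tolerant tail matching is attempted because no
  principled correction rule exists without a calibrated error model.

## Preprocessing

Adapter trimming removes the longest read suffix matching a prefix of the
3′ adapter (leftmost qualifying start), requiring overlap ≥ 3 and allowing
`floor(0.1 × overlap)` mismatches; both parameters are configurable. Reads
containing non-ACGT characters are dropped whole; post-trim reads < 15 nt
are dropped. No quality trimming is performed. Every drop is logged with a
reason, and `input == kept + dropped` is asserted per run.

## Alignment

Affine-gap Smith–Waterman (Gotoh), default scores +2/−3 and gaps −5 to
open, −2 to extend (a length-L gap costs −5 − 2(L−1)). The defaults are the
package's own choice of a conventional short-read scheme; they are
configurable and pinned by tests. Both orientations are aligned and the
better passing alignment kept; antisense survivors are counted but excluded
from classification. Filters (all configurable, defaults as in the study
conditions): length fraction ≥ 0.8 (aligned read bases over full read
length), similarity fraction ≥ 0.8 (matches over alignment columns,
gap columns included), ≤ 2 mismatch columns, ≤ 3 gap *events*. The
"events, not bases" reading of the indel budget, and the two fraction
definitions, are interpretation choices documented here precisely because
other readings exist; the monotonicity property (tightening any threshold
never admits more reads) holds under all of them.

Determinism: among co-optimal end cells the smallest window index, then the
smallest read index, wins; traceback prefers aligned columns over gaps and
closes gaps as early as possible. The DP fill is numba-JIT-compiled when
numba is importable, with an identical pure-Python fallback. Tests compare
scores against an independent oracle (top-down recursion over all alignment
continuations, itself validated against truly exhaustive operation-path
enumeration on tiny inputs).

## End annotation and classification

From the alignment columns, the covered gene interval `[gene_start,
gene_end]` is the span of aligned (match or mismatch) columns inside the
gene body. Read bases outside it are 5′/3′ extras. An extra base counts as
*genomic* if it is aligned within the flank (mismatches included: a trailer
with a sequencing error is still a trailer) contiguously from the gene
boundary outward; soft-clipped bases extend a genomic run only by exact,
contiguous comparison against the flank, and an insertion breaks the run.
The residual `tail = three_extra[three_genomic_len:]` is the inferred
post-transcriptional addition.

Category precedence: any genomic extension → I; else full-length (1–71)
with tail ∈ {"", CCA, CC, other} → II/III/IV/VIII; else 3′-tRF
(gene_start ≥ 2, gene_end = 71, tail ≠ "") with the same tail vocabulary →
V/VI/IX; everything else → VII. Species the category definitions do not
place explicitly are routed deterministically and flagged rather than
guessed away: single-C tails (`single_c_tail`, → VIII/IX), tail-less
fragments ending exactly at 71 (`three_trf_no_tail`, → VII), tails on reads
ending before 71 (`tail_on_truncated_3end`, → VII), and reads whose
downstream flank begins with C (`flank_c_ambiguity`), where a genomic
trailer is indistinguishable from the first base of a CC/CCA tail. One or
more genomic bases suffice for category I.

## Aggregation

Counts are exact integers and partition the mapped total per sample
(asserted). Percentages divide by the classified (I–IX) total by default —
UNCLASSIFIED is reported separately — and pooling sums counts across
replicates before dividing (used for the dormant-spore profile, which the
source study reports from the two T0 runs jointly). Replicate aggregation
reports the arithmetic mean and SEM = sd(n−1)/√n per (condition, time,
category); with one replicate the SEM is NaN, never 0. No hypothesis test
is attached: with n = 2 replicates per cell, means ± SEM are the honest
summary. Outputs are a wide TSV (byte-deterministic), per-category trend
plots with SEM bars, per-read calls, and a stage-accounting run log.

## Synthetic data generator

`generate_reference(seed)` draws a random 71-nt gene inside 60-nt flanks.
`simulate_sample` draws each read's category from the configured mixture,
builds the sequence by the category's definition (precursor leaders and
trailers are genuine flank sequence with geometric(p = 0.3) lengths on
{0, 1, 2, …}, at least one side non-empty; 3′-tRF starts uniform over
2…57; 5′-tRF ends uniform over 15…70; internal fragments ≥ 15 nt within
2…70; aberrant tails drawn from {CCAC, CCACA, CCACCA, CCA+poly(A) with 1–6
As, C, CA}), applies iid substitutions at the configured error rate, and
emits FASTQ plus a truth TSV. The default dormant-spore mixture is the
published category profile normalized to a probability vector (the printed
percentages sum to 99.59); the V/VI and VIII/IX splits are not printed
separately, so V/VI is split evenly and the VIII/IX split follows the same
convention used for the test mixture. Outgrowth defaults are qualitative
(precursors and 5′-tRFs up, CC-ended species down) and illustrative only.
Default per-sample depths mirror the published per-run mapped-read counts
(243–1141 reads), i.e. the study's own scale.

Two constructive guarantees make truth recovery exact at error rate 0:

1. **Flank constraint.** The first 12 bases of the downstream flank are
   drawn from {G, T} only. All tail strings are over {C, A}, so every tail
   column mismatches the flank and local alignment always soft-clips the
   tail; without this, a tail such as CCA against a flank like `TCA` would
   extend the alignment with net positive score (−3 + 2 + 2) and be
   miscounted as genomic trailer. This is strictly stronger than merely
   requiring the flank not to begin with C, which is insufficient under any
   scoring where two matches outweigh one mismatch.
2. **Mappability by construction.** Reads satisfy the default filters:
   fragments are ≥ 15 nt, and a fragment carrying an aberrant tail is at
   least 4× the tail length, so the 0.8 length fraction holds even for
   9-nt poly(A) tails. Without this, long-tailed short fragments would be
   silently unmapped and deplete category IX.

What the generator does **not** emulate: realistic quality profiles, ligation
and PCR bias, modification-induced truncation, and genomic contexts whose
downstream flank starts with C (the ambiguous case is flagged, not
simulated). Passing the truth-recovery tests therefore demonstrates that the
*classification logic* is exact under unambiguous constructions, not that
real-data category calls are error-free — on real data the flank-C ambiguity
and RT fall-off remain irreducible caveats.

At error rate 0.01 the degradation is mechanistic and tested: ~7
error-sensitive read positions (the two bases at each read end, and the
tail) move a mature read to V/VII/VIII; a first-tail-base substitution that
happens to equal the flank base legitimately aligns into the flank and
yields a rare (< 1%) category-I call. Errors can never fabricate a 5′
genomic leader, because a clipped end base is compared against the window
base adjacent to the alignment, which a substitution by definition no
longer matches.

## Problem sizes and numerics

The bundled experiments use a 191-nt window, reads of 15–95 nt, 10,000-read
truth-recovery corpora and two 5,000-read replicates for the pipeline-level
profile — comfortably larger than the study's own per-run depths while
keeping the full suite fast. Alignment scores are exact integers; the
traceback tie-break makes all outputs reproducible byte-for-byte for a
fixed seed. Percentage identities use floating point with a 1e-9 tolerance
on the sums. Single-replicate SEM is NaN by design; degenerate inputs
(empty FASTQ, zero-read samples, flank-only reads, unalignable reads) are
handled and tested rather than rejected.

## Known limitations

- Exact replication of the source study's read counts is not promised: the
  original preprocessing/mapping used a commercial toolchain whose precise
  trimming and gap-accounting defaults are not public; the filters here
  implement the published thresholds under documented interpretations.
- Where single-C tails and tail-less 71-ending fragments belong is not
  specified by the category definitions; the package's routing (VIII/IX and
  VII respectively) is deterministic and flagged per read.
- The outgrowth aggregation printed in the source ("average mapped reads"
  per subpopulation) is ambiguous between averaging over samples, times or
  conditions; the time-course table reports per-(condition, time) means so
  any of the three can be derived.
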