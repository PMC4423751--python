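# Methods

## Reference and index

The reference is an ordered list of contigs concatenated into one
0-based global coordinate space (SAM emission converts to 1-based).
The FM-index stores the BWT of `text + $`, the cumulative-count C
array, occurrence counts checkpointed every `occ_rate` positions
(default 64) and suffix-array values sampled every `sa_rate` rows
(default 8); both rates are serialized in the index header. Suffix
sorting uses prefix doubling (O(n log n) with numpy lexsort), which is
ample at the tens-of-megabases scale this package targets; no SA-IS
construction is attempted. `locate` walks the LF mapping to the nearest
sampled row, so its cost is bounded by `sa_rate`.

N bases get a dedicated alphabet code that no query base ever equals:
runs of N are invisible to seed matching, while DP scores N against
anything (including N) as a mismatch. Contigs are concatenated without
per-contig separators; a seed straddling a contig junction can nominate
a chimeric candidate, but windows are clamped to the candidate's contig
and DP rejects such placements. Only the forward text is indexed; the
reverse strand is handled by searching the read's reverse complement,
which doubles seed queries but keeps one index.

## Seeding

Seeds tile from the 5' end with step `seed_length − seed_overlap`, plus
one final seed anchored flush at the 3' end when the last tile would
overrun. The default round schedule is (140, 0, 1000), (80, 0, 1000),
(46, 0, 100) — long seeds first to keep candidate lists short, short
seeds later for sensitivity on reads with several mismatches or an
indel. A seed whose occurrence count exceeds the round's limit is
dropped as repetitive.

The backward search classifies each failed extension step: exactly one
continuing base is a *non-branching mismatch* (forced correction, no
fork), two or more continuing bases are *branching mismatches* (each
explored branch costs one BM). When the read base itself continues
alongside alternatives, the matching branch is free and each
alternative costs a BM. Budgets default to 1 BM + 2 NBM per seed.
Whether an NBM may occur at the very first (rightmost) character is a
genuinely open choice; we allow it, since the classification rule
applies uniformly at every step. Positions are deduplicated keeping the
lowest mismatch count; hits on the same diagonal (projected read start
within 8 bp) merge into one candidate region with ±16 bp of indel
margin around the read span. The merge tolerance and margin are wide
enough for the short (≤ a few bp) indels the DP window must absorb
while keeping windows, and hence DP cost, small.

Quality-aware seed placement: a seed spanning a base with quality below
Q13 is shifted so the suspect base lands on a seed boundary when an
in-bounds shift clears the span, otherwise it is kept as tiled. This is
a deliberately conservative heuristic for keeping likely errors and
variant positions out of indel-intolerant seed matching; it is
experimental and disabled by passing a `None` floor.

## Dynamic programming

Alignment is local over the read: affine-gap Gotoh with three tables
(M/I/D), a zero floor in M, free soft clips on both read ends and free
reference flanks. The first gap base costs `gap_open + gap_extend`.
Defaults (match +1, mismatch −2, open −3, extend −1) follow common
short-read practice and are fully configurable. Under this model a
mismatch within two bases of a read end is clipped rather than paid
for, which can shift the reported start by at most that distance —
well inside the ±5 bp evaluation tolerance.

The table is stored in anti-diagonal order as one flat array (the
(i, j) → offset map is a bijection, tested); each cell packs its three
scores into one 64-bit word as three 21-bit biased fields, so loading a
wavefront touches three contiguous vectors. Packing saturation raises
rather than wrapping. Wavefronts are processed in lane-sized chunks
(default 16) inside a numba kernel; because the arithmetic is exact
integer arithmetic with no intra-wavefront dependencies, results are
bit-identical for any lane width — asserted for lanes 1/4/16.

Traceback prefers M over D over I at every tie and, among equal-scoring
end cells, the smallest reference then read coordinate; with the zero
floor, a path whose remaining prefix contributes nothing terminates
there (clip) rather than extending through a zero-sum gap. These rules
make output deterministic byte-for-byte. An alignment is accepted when
its score reaches `match · read_len · 0.3`; reads whose best local
score is non-positive are unmapped. MAPQ is
`60·(best − second)/best` over the distinct loci scored for that read,
0 when the best is ambiguous, 60 when unique — a pragmatic confidence
score, not a calibrated error probability.

## Pairing and rounds

Candidate regions from the two ends are paired *before* any DP: same
contig, FR orientation (forward mate leftmost) and implied template
length inside `mean ± n_sd·sd` (defaults 500, 25, 4; CLI-settable, no
auto-estimation pass). Only the top 10 pairs by seed support are
verified by DP per round. A pair stops descending rounds at the first
proper pair; when all rounds fail, the best single-end placement
anchors a windowed mate rescue across the insert band, and failing
that, ends are reported independently (mate-unmapped flags). Rescue is
deliberately deferred until seeding is exhausted so that the round in
which a read resolves reflects its own seeds, not its partner's.
Proper-pair status (SAM flag 0x2) means: both ends accepted, one
contig, FR layout, template length in band — re-derived from the final
DP positions, not from the candidate pairing.

## Pipeline

Reads stream in batches (default 10^6 pairs; tests use small batches to
exercise boundaries). Each read pair is an independent work item;
worker processes operate on contiguous chunks and results merge in
input order, so output is byte-identical for any worker count. SAM
output is text with @HD/@SQ/@PG headers, the 11 mandatory fields,
standard flag bits, signed TLEN (leftmost positive), and tags AS
(score), NM (edit distance) and XR (resolving round). pysam is used
for reading/validating SAM, never for writing it, so validation stays
independent of emission.

## Synthetic data and evaluation

The generator emulates Illumina-style paired-end sequencing: i.i.d.
base composition at a target GC (default 0.41, human-like), optional
donor with SNPs and 1-3 bp indels (exact donor→reference lift-over
arrays), FR fragments with Gaussian insert length (default 500 ± 25 bp,
clamped to the read length), uniform per-base substitution errors
(default experiments use 0.5%), and a constant-Q30 quality profile with
an optional low-quality (Q10) fraction to exercise quality-aware
seeding. Truth is recorded per mate in reference coordinates.

What it does not emulate: position-dependent error rates, indel
sequencing errors, quality-correlated errors, coverage bias,
repetitive/low-complexity structure beyond what i.i.d. sequence
produces, and structural variants. Passing the recovery tests therefore
demonstrates algorithmic correctness of seeding/pairing/DP on
realistic error loads, not performance on real genomes with repeats —
on repeat-rich references the candidate limits and MAPQ ambiguity
handling matter much more than these tests can show.

Evaluation counts a mapped read correct when contig and strand match
truth and the reported 0-based start is within ±5 bp. Sensitivity is
correct / all reads (the aligner emits one primary record per read,
unmapped included); FDR is incorrect / aligned. Problem sizes used
throughout (100 kb genomes, 2,000-pair runs, 500-instance oracle
sweeps) were chosen as the smallest scales at which every code path —
multi-round descent, overflow, rescue — is exercised with stable
statistics.

## Numerical and degenerate-input choices

- Packed-cell fields hold |score| ≤ 2^20−1; the gap-state floor is
  −2^19, large enough that clamping never alters reachable cells for
  reads ≤ 1,024 bp (the configured maximum) at any sane scoring.
- Empty reference, non-ACGTN characters, mate-count mismatches,
  truncated index files and unknown read ids all raise with the
  offending location named.
- All-N reads produce no seeds and are emitted as unmapped records;
  windows near contig edges are clamped (and re-widened inside the
  contig when shorter than the read).
- Every tie in seeding, pairing and traceback has a documented
  deterministic resolution; fixed seeds + fixed config give
  byte-identical SAM (modulo the @PG command line).
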