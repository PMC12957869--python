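# Methods

## Sequence-Levenshtein barcodes

Barcodes read out by sequencing are embedded in longer DNA: the read
continues past the barcode into fixed construct sequence. An indel
inside the barcode therefore shifts construct bases into the decoded
window rather than truncating the word. The sequence-Levenshtein (SL)
distance models this by relaxing the right boundary of the edit-script:
SL(a, b) is the minimum over the entire last row and last column of the
unit-cost Levenshtein DP matrix, i.e. the cheapest script in which
either word may end early. SL is symmetric and never exceeds the plain
Levenshtein distance. It is **not** a metric (the triangle inequality
can fail), which has a practical consequence for decoding discussed
below.

Pools are generated with the greedy lexicographic (Conway) closure:
every word of length L is enumerated in A < C < G < T order; words
failing a composition filter are skipped; a word is accepted iff its SL
distance to every previously accepted word is at least d_min. The
construction is fully deterministic — a pool is reproduced exactly from
(length, d_min, filter set) — and the closure guarantees the pool
minimum distance by construction. Composition filters (each
individually toggleable):

- **triplet** — no homopolymer run of length ≥ 3 (synthesis and
  sequencing fidelity);
- **gc** — GC fraction within [0.4, 0.6], boundaries inclusive
  (uniform amplification/melting behavior);
- **selfcomp** — the word is not its own reverse complement (hairpin
  avoidance; only possible at even lengths).

Defaults are length 12, d_min 4, all filters on. A distance-4 code
detects up to 3 edits and corrects 1 (detect = d_min − 1, correct =
⌊(d_min − 1)/2⌋). Filters are applied before closure membership
testing; applying them after the closure instead changes the resulting
pool (the closure set depends on which words are available when), so
the filter stage is part of the pool's identity. Screening subsets are
chosen by greatest mean pairwise SL distance against the full pool,
ties broken lexicographically.

The inner DP short-circuits: row minima of the Levenshtein matrix are
non-decreasing, so a pairwise comparison is abandoned as soon as the
current row minimum and the running last-column minimum both reach
d_min. With the numba-compiled kernels the full 4¹² closure is a
tens-of-minutes, one-CPU job and the 200-barcode early-stop run takes
seconds;
tests and the acceptance script use the early-stop pool (200 barcodes),
a problem size chosen so the whole suite runs comfortably on a laptop.

## Read decoding

Reads are assumed demultiplexed, single-end, and oriented so the
barcode precedes the clamp (a `reverse_complement_reads` flag covers
the opposite orientation). The layout is

    [fixed 3'-UTR tail] [barcode] [clamp] [12-nt UMI]

The clamp is located by sliding edit-distance alignment with at most
`max_clamp_edits` edits (default 1, mirroring the code's correction
radius). The best alignment is the one with the fewest edits, ties
resolved to the leftmost start; minimizing position before edit count
would systematically anchor one base early, since deleting the clamp's
first base always yields a 1-edit match one position upstream.

The barcode window is the barcode_length + slack bases 5′ of the clamp
(slack default 3 = the detection bound, absorbing indel shifts; the
slack sits 5′ because the clamp pins the 3′ end). Decoding computes,
for each candidate, the embedded distance anchored at the
clamp-proximal end: DP over the reversed candidate versus the reversed
window, candidate fully consumed, window free-ended. Assignment
requires a unique minimum within the correction radius; ties are
reported `ambiguous` and dropped — a wrongly assigned read biases the
screen, a dropped read only costs depth. A window whose clamp-adjacent
12-mer equals a pool barcode exactly is assigned at distance 0 without
further scoring.

Because SL is not a metric, a d_min = 4 closure does not strictly
preclude radius-1 ties in embedded context: in the default 200-barcode
pool, 3 of the 20 000 possible single-edit corruptions produce a
shifted alignment of a *different* barcode at distance 1 (11 window
bases matched with one edit). The assay's construct makes the upstream
sequence known, so when `fixed_prefix` is provided the decoder scores
the window's residual 5′ bases against it (window fully consumed,
candidate+context free-ended). This separates the impostor — its
alignment leaves upstream bases unexplained — and restores exhaustive
100% single-error correction, verified over all 20 000 corruptions.
Without a known prefix the rare ties surface as `ambiguous`.

N bases mismatch everything, including N. Reads whose UMI contains an N
count toward raw reads but are excluded from UMI collapse. Base
qualities are ignored: the distance-4 code already provides the stated
guarantee.

UMI collapse uses the directional network rule: UMIs are processed in
descending count (ties lexicographic); u absorbs a Hamming-1 neighbour
v when count(u) ≥ 2·count(v) − 1, transitively; molecules = number of
cluster roots. A `unique` mode counts distinct UMIs instead. The
directional rule is the default because single sequencing errors on an
abundant UMI produce satellite UMIs at roughly half its count or less.

## Quantification and narrowing

Read fraction: barcode count / sample total (undefined for an all-zero
sample). Normalized accumulation: output fraction divided by the mean
fraction over uninjected input-pool samples. Barcodes with zero mean
input fraction have no defined NA; they are flagged and excluded from
downstream statistics rather than rescued with a pseudocount (a
`pseudocount` would invent signal where the input pool saw none). NA is
also computed for the input samples themselves, where its per-barcode
mean is identically 1 — a useful internal consistency check.

Group summaries are arithmetic mean and sample SD (ddof = 1) of NA over
the samples of each group. Profile correlations are Pearson
correlations across barcodes of the group-mean NA vectors; a profile
with (numerically) zero variance — e.g. the input group — has no
defined correlation and is reported as missing.

Narrowing: for each barcode, its NA values over the scope's samples are
tested against the pooled NA values of all other barcodes with a
Wilcoxon rank-sum test (normal approximation: mid-ranks, tie-corrected
variance, continuity correction of 0.5 toward the null mean; fully tied
data degenerate to z = 0, p = 1), and p-values are BH-adjusted across
the barcodes of the run. The exclusion decision is driven by the
effect-size rule: mean NA outside the inclusive window [0.8, 1.2]
(±20%) excludes a barcode as enriched or depleted; q-values are
reported alongside, and a `require_significance` switch makes the rule
conjunctive (deviation AND q < alpha). The default scope pools all
non-input samples; `per-group` scope excludes a barcode deviating in
any single group, for screens where tissue-specific bias matters.

Small-sample caveat: the normal approximation is exact enough for the
pooled narrowing comparison (n₂ in the hundreds), but at tiny equal
group sizes its two-sided p can deviate from the exact permutation
p by up to 0.088 (n = 2), 0.038 (n = 3), 0.031 (n = 4); from n = 5 the
worst case is below 0.02. This is intrinsic to the approximation (the
implementation matches scipy's asymptotic Mann-Whitney p to 1e-10);
below n = 5 an exact test would be preferable, but the approximation is
retained as the platform's prescribed procedure.

Tropism classification is a threshold rule on already-quantified
luminescence: spleen-tropic iff spleen:liver ratio strictly exceeds the
PBS-control baseline ratio; equality classifies as liver-tropic, fixing
the boundary the verbal rule leaves open.

## Simulator

The simulator emulates the screen's data-generating process, not its
biology: per-sample molecule counts are multinomial over the
(effect-adjusted, renormalized) barcode abundance vector; planted
enrichment effects are fold multipliers applied only to non-input
samples; each molecule gets a uniform random 12-mer UMI (collisions
possible and tolerated); PCR duplication draws a geometric count with
the configured mean (≥ 1, a one-parameter overdispersed choice — the
platform specifies no PCR model); reads are prefix + barcode + clamp +
UMI corrupted by independent per-base substitution/insertion/deletion
(errors fall on all segments, so clamp errors exercise approximate
anchoring); the quality string is a constant 'I' since qualities are
ignored downstream. `depth` is the number of molecules sampled (equal
to reads when duplication is 1).

Per-sample RNGs derive from (scenario seed, sample index), so each
sample's reads are reproducible independently of which other samples
are generated; FASTQ bytes and ground-truth tables are deterministic
given the seed.

What the simulator does not model — and what passing tests therefore do
not show about real data: tissue uptake biology, sequence-dependent
amplification bias, instrument-specific error profiles (errors here are
uniform and independent), chimeric reads, and index hopping. The
round-trip and power results certify the pipeline's correctness on its
stated model, not the wet-lab assay.

Default test/acceptance problem sizes: 200-barcode pool; null and
power screens use 2 input + 4 output samples at 5×10⁴–10⁵ molecules
per sample; planted folds 1.5×/0.6× are detected with ≥ 95%
probability at that depth.

## I/O and determinism

All tabular artifacts are TSV (UTF-8, LF, newline-terminated), written
in deterministic order; pipeline reruns with the same config and seed
are byte-identical. Pools round-trip through FASTA (ids `bc<rank>`,
rank = 1-based generation order) or TSV (with an optional
mean-pairwise-distance column); the minimum pairwise distance is
recomputed on load and checked against any declared value. Sample
sheets are TSV with columns sample_id, group, is_input_pool, replicate.
FASTQ input may be gzip-compressed; structurally broken FASTQ records
are counted as malformed and skipped without aborting the stream.
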