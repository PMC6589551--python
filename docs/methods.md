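# Methods

## The discovery model

`combimotif` is a discriminative, word-based motif finder for ChIP-seq peak
sets. The statistical unit throughout is the *sequence*, not the
occurrence: a k-mer's evidence is the number of foreground sequences that
contain it (on either strand) versus the number of background sequences
that do, and every later quantity — motif p-values, combination supports,
co-occurrence tests — is derived from unions and intersections of those
per-sequence index sets. This makes the model robust to repeat-driven
occurrence inflation inside single peaks, at the cost of saturating for
very short words in long sequences (see Limitations).

The pipeline:

1. **Read / background.** Foreground peaks from FASTA. If no background is
   supplied, one is generated i.i.d. from the foreground mononucleotide
   composition, one background sequence per foreground sequence at the same
   length. N bases are retained in sequences but excluded from composition,
   and any k-mer window containing an N is skipped.
2. **Index.** For every width k in `[k_min, k_max]` (default 5..10), both
   sets are scanned into maps from *canonical* k-mer (lexicographic min of
   the word and its reverse complement, so both strands share one key) to
   the sorted array of distinct sequence indices containing it.
3. **Enrichment.** Each foreground k-mer gets a one-sided Fisher exact
   p-value: the upper hypergeometric tail of the 2×2 table
   (a of n_fg foreground vs c of n_bg background sequences). All p-values
   live in natural-log space end to end; tails are log-sum-exp sums over
   exact/cumulative log-factorials, so values far beyond double-precision
   underflow (p ~ 1e-300 and below) remain exact in the log domain and are
   only *rendered* in scientific notation (with a `<1e-320` display floor).
4. **Seeding and growth.** Significant k-mers (p ≤ 0.05) are sorted
   ascending by p into an array A (ties broken lexicographically). Seeds
   are taken from the top of A and each is grown greedily: scanning A
   forward, a candidate joins the motif when (a) it is Hamming-distance 1
   from an existing member in some orientation, (b) the motif keeps at most
   `floor(alpha*k)` non-conserved positions (alpha = 0.30), and (c) the
   Fisher p of the unioned support stays below beta = 0.05. The first
   (a)+(b) candidate that fails (c) terminates growth.
5. **Profiles.** PFM columns are support-weighted member counts (each
   member contributes its foreground sequence count) plus a Laplace
   pseudocount; PWM is log2 odds against the (smoothed) background
   composition; position information content is `2 + sum f log2 f`, in
   [0, 2] bits.
6. **Merge / dedup.** Equal-length motifs merge under complete-linkage
   grouping at A-score ≥ 0.7; redundancy across all lengths is removed by
   iteratively deleting the higher-p member of the most similar pair until
   every surviving pair has B-score ≤ 0.6.
7. **Combinations.** All pairs (by default; subsets up to `combo_order`) of
   the final motifs are scored by Fisher's combined probability test,
   chi² = −2·Σ ln p with 2u degrees of freedom, evaluated through the
   even-df closed form in log space. The combination statistic aggregates
   the members' individual enrichment; joint occurrence is reported
   separately as a one-sided hypergeometric overlap test on the two
   foreground support sets.

## Seeding across lengths

Seeds could be drawn from a single mixed top-m list or per width. We split
the m = 100 seed budget evenly across widths (ceil(m / #widths) per k,
`--mixed-seeds` restores the single list). In a mixed list the most
enriched width monopolises every seed — log-p values grow roughly linearly
with word length for fixed effect size — and motifs at the other widths
can then never be discovered, which defeats a multi-width finder. The even
split keeps the total growth cost of the m = 100 default unchanged.

## The profile-similarity metric

Motif-vs-motif similarity is an information-content-weighted cross score:
column i contributes

    s_i = IC_x[i]·(f_x[i]·w̃_y[i]) + IC_y[i]·(f_y[i]·w̃_x[i])

where f are PFM columns and w̃ are PWM columns *centred to zero mean* over
the four bases. Centring matters: a raw log-odds column has a strongly
negative mean (rare bases carry large negative weights), which would push
every unrelated pair toward −1 instead of 0. The summed score is
normalised by the geometric mean of the two self-scores computed on the
same columns, giving 1 for self-comparison and ~0 in expectation for
unrelated informative profiles.

* **A-score**: equal-length profiles at offset 0, maximum over the two
  orientations of the second motif. Used for merging (threshold 0.7).
* **B-score**: maximum over both orientations and all ungapped offsets with
  overlap ≥ max(4, ceil(min_len/2)); each window's normalised score is
  additionally weighted by overlap/min_len so a full containment still
  scores 1 but a chance agreement over a minimal window cannot win the
  max. Used for redundancy deletion (threshold 0.6) and for all
  evaluation statistics.

Calibration (reproducible via `combimotif.similarity_calibration`): when a
random informative profile's sites are split into two halves, the two
half-profiles (noisy estimates of one parent) score ~0.9 median against
each other, while halves of different parents score ~0.3 median — a gap
comfortably spanning the 0.6/0.7 thresholds. The exact formula is isolated
behind `column_score`/`a_score`/`b_score` so an alternative metric can be
swapped in without touching the pipeline.

## Synthetic benchmark

`implant_benchmark` emulates peak simulation: background sequences are
drawn from an order-3 Markov chain, and one site sampled column-wise from
a reference PFM is written over the background bases at a uniform random
position and strand (replacement keeps sequence lengths exact). Exactly
one implant per sequence is recorded as ground truth.

Where no training sequences are available, `random_markov_model` draws
Dirichlet(10) transition rows: conditional probabilities deviate ~25–30%
from uniform, about the magnitude of genomic di-/trinucleotide structure
outside CpG. Stronger structure (e.g. Dirichlet(5)) makes chain-favoured
words compete with the implant for the top ranks — a genuine property of
any finder whose default background is mononucleotide-i.i.d., worth
remembering when interpreting top hits on strongly structured inputs.

What the generator does *not* emulate: positional bias of sites within
peaks, multiple/missing sites per sequence, flanking-sequence homology,
and real cross-TF motif families. Passing benchmarks here demonstrate the
machinery recovers planted signal under the stated noise model, not
performance on any particular real dataset.

Evaluation statistics (`benchmark_eval`): **PA** is the fraction of
datasets whose top predicted motif matches some reference profile of the
dataset's TF with B-score above gamma (0.6 by default); **ARR** is the
number of each TF's reference motifs recovered by the top-10 predictions,
normalised by sum over TFs of (datasets × references); the **ROC** treats
prediction rank as the sweep score: at cutoff r = 1..20, TPR is the
fraction of datasets whose truth is matched at rank ≤ r and FPR the
fraction of all non-matching predictions already emitted at rank ≤ r,
with AUC by trapezoid and the curve closed at (0,0) and (1,·). This is the
standard rank-sweep construction — a finder that places every truth in its
top few ranks scores near 1 even when rank 1 is occasionally taken by a
background-composition motif, while a finder that never matches scores 0.

## Numerical and determinism choices

* Log-factorials: exact big-integer table for n ≤ 170, cumulative log
  extension above (agrees with log-gamma to ~1e-12 at n = 1000).
* All tail sums (hypergeometric, chi-square) are log-sum-exp in a fixed
  ascending order, so results are bit-identical across runs and worker
  counts.
* Parallel stages (per-k scans, per-k-mer tests, per-seed growth, per-pair
  scores) decompose into independent units whose results are assembled in
  a canonical order; `find` output files are byte-identical for any
  `-t/--workers` value.
* Degenerate inputs: a p of exactly 1 renders as "1"; uniform profiles
  have zero information and score 0 similarity by convention (self-score
  below 1e-9); composition is smoothed (+1 per base) before log-odds so a
  base absent from the input cannot produce −inf.
* Tie-breaks: seed ordering breaks p ties lexicographically; deduplication
  removes the later-ranked motif on equal p; candidate orientation prefers
  the forward (canonical) strand.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the benchmark at 10
datasets × 1000 sequences × 1000 bp (one dataset per implanted PFM of
width 5..10) and the recovery check at 20 replicates of 1000 × 500 bp —
sizes at which every stage's statistical behaviour is already asymptotic
while a full run stays in the minutes range on one core.

## Limitations

* Per-sequence presence saturates for short words in long sequences: a
  specific 5-mer is already present by chance in ~86% of 1000-bp
  sequences, so width-5 motifs carry weak contrast at moderate sample
  sizes and rank below longer motifs (they are still found via the
  per-length seed budget, at lower ranks).
* The similarity metric is a reconstruction calibrated to documented
  behaviour (self ≈ 1, unrelated ≈ 0, sub-motif pairs high); absolute
  threshold values 0.7/0.6 may need recalibration if a different metric
  is swapped in.
* No PWM rescanning/EM refinement: motifs are unions of near-identical
  significant words by design; degenerate motifs whose instances differ at
  more than `alpha·k` positions will fragment.
* Combination p-values combine member enrichment and are not corrected for
  the number of combinations enumerated; the separate co-occurrence test
  should be consulted before interpreting a pair as co-binding.
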