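# Methods

## Model and assumptions

readscrub treats read quality as locally varying: a long read is a mosaic
of ordinary segments (errors at some baseline rate) and occasional
low-quality stretches — clustered "junk" segments and chimeric junctions —
that downstream assembly is better off without. The observable used to find
them is *read-to-read support*: a k-mer covered by many other reads is very
likely correct, one supported by none is likely erroneous. Minimizer
sketches make this tractable at all-vs-all scale, and encoding the support
pattern as an image lets a convolutional network learn the mapping from
support, quality scores, and inter-minimizer spacing to segment percent
identity, without base-level alignment and without a reference at
prediction time.

Key assumptions: errors are frequent enough that exact alignment is
unreliable but minimizer co-occurrence is informative; coverage is high
enough (roughly ≥ 10×) that true segments have overlapping support; and the
error profile at prediction time resembles the one trained on.

## Coordinates and conventions

All coordinates are 0-based, half-open. Strand is `+`/`-`. Identity values
are fractions in [0, 1]. Quality strings are Phred+33 throughout.

## Minimizers

`minimizers` extracts (w,k)-minimizers (defaults w=5, k=15; the alternative
setting (7,17) is tested too). The order key is a SplitMix64 avalanche of
the 2-bit-encoded *canonical* k-mer (minimum of forward and reverse
complement), so sketches are strand-agnostic and homopolymers are not
systematically preferred the way plain alphabetical order prefers poly-A.
Ties within a window select every tied occurrence, which keeps the
window-sharing guarantee exact. k-mers containing non-ACGT characters are
ineligible; windows are formed over the remaining valid k-mers, so isolated
Ns shrink windows rather than voiding whole regions. A brute-force
enumerator (`brute_force_minimizers`, scalar arithmetic, no sliding-window
optimization) ships as a first-class oracle and the suite asserts exact
equivalence on random sequences across four (w,k) settings.

## Overlapping and chaining

Every read serves as reference once; candidate matches are grouped per
(query read, relative strand) from a hash → occurrences index. Minimizers
occurring in more than 200 reads are skipped as repeats (quadratic blow-up
guard; configurable). Chaining is a longest-increasing-subsequence over
shared occurrences — strictly increasing reference index, query positions
increasing (same strand) or decreasing (opposite) — with consecutive
chained matches at most `max_gap` = 500 bases apart on both reads. Pairs
with fewer than `min_shared` = 4 chained matches are suppressed. This is
deliberately simpler than a production overlapper's scored chaining:
downstream only consumes matched minimizer positions, and LIS is exactly
testable against explicit enumeration. A fast path returns the whole
candidate set when it already forms a valid chain (the common case for
clean overlaps). Standard PAF from an external overlapper can substitute
for the native pass; matched positions are then recovered by intersecting
the two sketches inside the PAF interval and chaining as above.

## Pileup encoding

One image per reference read: rows = reads (row 0 the reference, up to 23
matching reads, sampled uniformly without replacement under `rng_seed` when
the pile is deeper; matching reads are first ranked by shared-minimizer
count so shallow piles keep the most informative reads), columns = the
reference read's minimizers. Channels:

* red — 255 where the row's read contains the column's minimizer, 70 inside
  its matched span otherwise, 0 outside;
* green — 2 × mean quality character (ASCII) over the pixel's base
  interval, clamped to [66, 254] (quality `'!'` = 33 maps to 66; the upper
  clamp at 254 nominally admits ASCII 127, one beyond the usual `'~'` =
  126 → 252);
* blue — base distance to the next minimizer, clamped at 255; row-to-row
  disagreement in blue is the indel signal.

For a matching read, base positions at columns where it lacks the minimizer
are inferred by linear interpolation between the flanking matched
minimizers — this keeps green/blue defined across the whole matched span
without alignment. Column i covers the base interval from its minimizer
start to the next minimizer's start; the first column is extended back to
base 0 and the last runs to the read end, so that segment base ranges
partition the entire read (a requirement of the scrubbing stage).

Images are cut into consecutive 48-column segments; a final partial segment
is right-padded with black columns and its base range runs to the read end.

## Labels

Training labels are the fraction of a segment's *read* bases aligned as
exact matches: insertions, mismatches, clipped and unaligned bases count in
the denominator only; deletions consume no read base. One primary alignment
per read (most aligned read bases; secondary/supplementary ignored), so a
chimeric read scores low outside its primary locus — exactly the signal the
scrubber should learn. Ambiguous `M` CIGAR operations are resolved through
the MD tag when present; otherwise `M` counts as a match and a warning is
logged. Match counts are additive, so whole-read identity equals the
length-weighted mean of segment identities exactly; the suite asserts this.

## The regressor

Two architectures, both ending in a single sigmoid unit (identities are
proportions; the head bounds predictions to [0, 1]):

* `vgg16_adapted` — the classic 13-convolution (3×3 filters) /
  3-fully-connected layout with channel widths 64–512. A 24-pixel depth
  axis cannot survive five 2× poolings, so the last two poolings act on the
  length axis only. This is the fidelity target for large training runs.
* `small` — three convolution blocks (16/32/64 channels) whose pooling
  mostly collapses the *depth* axis while preserving column resolution
  (24×48 → 1×24 before the dense layers), plus one hidden dense layer.
  Per-column minimizer-survival detail is the strongest predictor of
  realized segment identity, and this variant trains in a couple of minutes
  on one CPU.

Training: Adam, mean-squared-error loss, Glorot-uniform initialization,
5 epochs and batch size 64 by default. The learning rate resolves per
variant: 1e-4 for `vgg16_adapted` (the published recipe, sized for long
training runs on large datasets) and 1e-3 for `small`, whose desk-scale
runs take roughly an order of magnitude fewer optimizer steps — at 1e-4 the
small variant is still visibly underfit after 5 epochs. Two further
optimization details: the sigmoid head's bias is initialized to the logit
of the mean training label, so the short epoch budget is spent on
discrimination rather than drifting toward the prior; and the returned
weights are the Polyak average over the final epoch's steps, damping SGD
noise in the last iterates. Training is deterministic given the seed
(weights, shuffles, and the by-read validation split all derive from it).
The validation split is made by reference read, not by segment, because
segments of one read are strongly correlated.

The convolution/pooling/dense stack itself is implemented in-package on
numpy (im2col convolutions, analytic gradients verified against numerical
differentiation in the suite); predictions and training are CPU-only and
single-threaded-deterministic.

Evaluation reports MSE, Pearson and Spearman correlation, and — at a chosen
identity cutoff, default 0.8 — sensitivity (truly-above-cutoff segments
retained) and specificity (truly-below-cutoff segments removed).
Zero-variance inputs yield NaN correlations rather than an error.

## Scrubbing

Segments predicted below the threshold (default 0.8) are removed whole (no
trimming into them); maximal runs of kept segments become fragments named
`<read_id>:<n>`; fragments shorter than `min_length` (default 500 bases) are
dropped. The length filter applies per fragment, after splitting — the
stricter of the two possible readings, consistent with scrubbing's goal of
removing short low-support pieces. A read whose full span survives is
emitted unchanged under its original id. A below-threshold final segment
(including any padded tail columns) removes through the read end. Reads
missing from the prediction table pass through unmodified with a warning.
Conservation (fragments + removed spans tile the read) and threshold
monotonicity (raising the threshold never increases retained bases) are
asserted over a thousand random prediction tables.

## Synthetic data

The simulator emulates the error structure the scrubber is designed for,
not any particular flowcell chemistry:

* genomes — uniform random ACGT of configurable lengths (default one
  50 kb genome);
* read lengths — log-normal, median 2 kb, σ = 0.72 (mean ≈ 2.6 kb),
  truncated to [200, genome length]; reads are drawn until the requested
  coverage (default 30×) is met;
* errors — baseline per-base rate 0.15, 60% of errors indels (half
  insertions, half deletions), the rest substitutions;
* junk segments — 30% of reads contain one 100–1000 base stretch whose
  error rate is drawn from [0.3, 0.5];
* chimeras — 5% of reads join two independent loci;
* qualities — per-base Phred drawn from a normal around −10·log₁₀(local
  planned error rate), sd 3, truncated to [0, 40], so the green channel is
  informative but imperfect: quality tracks the *planned* local rate, not
  the realized errors, mirroring why overlap support is needed beyond
  quality scores.

Ground truth records each read's source intervals, junk spans, and a
per-base error mask; truth labels are 1 − (error fraction in the segment's
base range). What the simulator does *not* reproduce: realistic genome
composition and repeats (uniform random sequence makes overlap detection
easier than in repeat-rich genomes), systematic homopolymer errors,
position- or sequence-dependent error profiles, and basecaller-specific
quality miscalibration. Passing tests on this data therefore demonstrate
that the pipeline recovers planted signal under the assumed error
structure, not performance on any particular real platform.

Within-segment realized identity also carries irreducible sampling noise
(a ~150-base segment at 15% error has a binomial identity s.d. of ~0.03
that no feature can predict), which bounds the achievable rank correlation
on the default conditions; the end-to-end recovery test runs close to that
ceiling.

## Problem sizes and numerical choices

The suite's end-to-end run uses one 50 kb genome at 30× (~550–750 reads,
~10k segments) with the `small` variant — sizes chosen so the whole suite
completes in minutes on one CPU while still exercising every stage at
realistic depth. Degenerate inputs are defined, not errors: reads shorter
than k yield no minimizers, an empty pile encodes only the reference row, a
sequence shorter than k yields an empty sketch, and an empty overlap set
serializes to a header-only file. Ties in a minimizer window select all
tied occurrences; ties at the scrub threshold are kept (`>=` retains).
Max-pooling routes gradient to every tied maximum. Model serialization is a
single `.npz` with embedded JSON metadata (variant, configs, seed);
save → load → predict is bit-identical.

## Known limitations

* Chaining is unscored LIS with a gap cap; a production overlapper finds
  more overlaps on hard reads (the PAF input path exists for exactly that).
* Junk segments and chimeric junctions are scrubbed identically;
  discriminating them (to split only chimeras and leave indel-rich
  segments to error correction) is future work.
* The numpy network is CPU-bound; the `vgg16_adapted` variant is practical
  only for small batches without an accelerator-backed framework.
* Labels from minimal SAM (`M` without MD) overestimate identity.
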