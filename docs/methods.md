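# Methods

## Data model

All coordinates are 0-based half-open. An `AlignmentRecord` carries the
scaffold, leftmost position, reference span, MAPQ, pool barcode (from the
`BX` tag, falling back to the `RG` read-group label) and the flag bits the
filters need. Interval sets (`GenomicIntervalSet`) are per-scaffold sorted
disjoint lists after normalization.

## Filtering and masking

Trusted alignments are properly paired, mapped, non-duplicate,
non-supplementary, with MAPQ strictly greater than `min_mapq` (default
10). The repeat mask is the union of the reference spans of alignments
with MAPQ ≤ `min_mapq`; the two sets partition the mapped stream exactly.
Mask intervals separated by fewer than 40 bp are merged — low-MAPQ
evidence for a repeat is locally bursty, and sub-40 bp unique islands are
too short to carry independent signal. N runs in the assembly are added
to the mask. Barcodes with fewer than 50 trusted reads are dropped: such
pools are too sparse to demarcate fragments or support links.

## Read-cloud statistics

Clouds are demarcated per (scaffold, barcode) as maximal runs of occupied
5 kb windows on scaffolds longer than 500 kb (shorter scaffolds truncate
fragments and bias the length distribution). The adjusted cloud length is
`(n_windows − 1) × window`: a run of w occupied windows is evidence for a
fragment at least spanning the w−1 inter-window gaps, so a single-window
cloud has adjusted length 0. Cloud density is the pooled ratio
Σreads / Σkb, not a mean of per-cloud ratios, so short clouds do not
dominate. Physical coverage is Σ(cloud lengths) × scaling / genome size,
where the scaling factor (all trusted reads over trusted reads on the
large demarcation scaffolds) corrects for clouds on scaffolds too short
to demarcate. N50/N10/N90 take the largest length at which the descending
cumulative sum reaches 50/10/90% of the total; NG50 uses an assumed
genome size instead of the assembly total and reports 0 when unreached.

## Scaffolding

Node windows grow inward from each scaffold end (binary search over the
monotone unmasked-base count) until they hold `E` = 10,000 unmasked
bases, capped at `o` = 50,000 bp; scaffolds under `m` = 5,000 bp are
skipped. A barcode joins a node's set when at least one of its trusted
reads starts unmasked inside the window. Node barcode counts above the
`D` = 0.985 upper quantile are removed (realized cutoff: smallest count c
such that the fraction of nodes with count < c is ≥ D; ties retained) —
oversubscribed nodes sit in collapsed repeats and link promiscuously.

For nodes A, B the ordered shared fraction is |A ∩ B| / |A|. Each node's
fractions against all other nodes are fitted with a normal distribution
(mean and standard deviation of the sample); the ordered score of an
observation is −log10 of its upper-tail probability under that fit,
computed via the log survival function so deep tails stay finite. A
node with zero sample variance is excluded rather than given an
artificial variance floor. The unordered pair score is the arithmetic
mean of the two ordered scores. The global edge threshold defaults to
the 99th percentile of pair scores among pairs sharing exactly one
barcode — one shared barcode is common by chance and never evidence of
adjacency, so calibrating on those pairs places the threshold just above
the coincidence regime.

Greedy layout visits edges in descending score (ties broken by node keys
for determinism) and accepts an edge iff both scaffold-end nodes are
unused and the scaffolds are in different chains (union-find; no cycles).
Orientation follows end polarity: exiting a 3′ end keeps a member
forward, entering through a 5′ end keeps the next member forward; chains
are canonicalized to start forward. Consensus concatenates members with
`gap_n` = 100 N spacers, reverse-complementing reverse members; the join
id records order and orientation (`join|a+|b-`).

## Calibration

Scaffolds ≥ 500 kb are split into children holding exactly 50 kb of
non-N sequence (the last child takes the remainder); a cut never lands
inside an N run — gaps attach to the preceding child — so concatenating
children reproduces the parent byte-exactly. Alignments lift by leftmost
base with spans clipped at child boundaries; masks split at cut points.
After rescaffolding the children, each made join is classified: adjacent
same-parent children are *correct*; two terminal children of different
parents are *ignored* (unverifiable); everything else is *type 1*. Every
true-adjacent pair left unjoined is a *type 2* miss. Rates:
type1 / (correct + type1) and type2 / (correct + type2), as percentages.

## Simulator

The generator emulates, at desk scale, one read-cloud library over a
repeat-rich genome:

- **Genome** (default 5 Mb): random sequence with repeat-family copies
  planted until 79% of bases are repetitive (copy lengths 500–3,000 bp,
  20 families). Mapping ambiguity — the repeat subset young enough to
  defeat unique alignment — is planted as short intervals (100–300 bp)
  placed uniformly over the merged repeat territory until it covers 48%
  of repeat bases. Keeping ambiguous runs short preserves sub-window
  unique anchors, which is what real clouds rely on; whole-copy ambiguity
  would fragment clouds at the 5 kb window scale.
- **Pools**: 512 barcodes, Poisson(3.7) fragments each, dropped uniformly;
  fragment lengths are lognormal with μ = ln 50,000 and
  σ = √ln(80,000/50,000), pinning a 50 kb median and an 80 kb
  length-weighted N50 (the length-weighted lognormal median is
  e^(μ+σ²)). Expected physical coverage ≈ 24×.
- **Reads**: Poisson placement along each fragment at a raw rate of
  `read_density / (1 − 0.79 × 0.48)` per kb, so the surviving trusted
  density is `read_density` (default 1.0/kb). Reads starting in ambiguous
  territory draw MAPQ ∈ [0, 10], others [30, 60]. PCR duplicates are
  emitted as additional flagged copies (1%), exercising the filters
  without eroding the density target.
- **Draft**: the genome cut into fixed-size pieces, shuffled and randomly
  re-oriented, with a truth table (order, offsets, orientations) that
  lifts reads into draft coordinates and labels any join as
  true-adjacent or not.

What the generator does **not** model: paired-end geometry (records are
single-end with a nominal span), chimeric fragments, barcode collisions
between molecules beyond pool sharing, GC or coverage bias, structural
error in the draft pieces, and real aligner MAPQ behavior (territory
membership decides MAPQ deterministically by range).

## Numerical choices and limitations

- Window demarcation quantizes cloud lengths to 2.5 kb steps in the
  median; at 1 trusted read/kb a 5 kb window is empty with probability
  e^−5 ≈ 0.7%, so even an ideal estimator reports medians of 40–45 kb
  for a 50 kb fragment median. Cloud medians from 5 kb windows should be
  read with ± one-window resolution.
- The normal fit to shared fractions is a pragmatic tail model, not a
  claim about the true distribution (which is closer to hypergeometric);
  the calibrated threshold absorbs most of the mismatch.
- The greedy layout is order-deterministic but not globally optimal; it
  matches an exhaustive greedy oracle, not a maximum-weight matching.
- `filter_nodes_by_barcode_count` clips only the upper tail; lower-tail
  clipping is unnecessary because sparse nodes already fail to form
  significant links.
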