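# cloudscaffold

Read-cloud scaffolding of fragmented draft genome assemblies.

Linked-read ("read cloud") libraries partition high-molecular-weight DNA
into barcoded subhaploid pools, so all short reads carrying one barcode
come from a few long fragments. When two draft scaffolds are physically
adjacent in the genome, fragments spanning the junction leave the same
barcodes near both scaffold ends. `cloudscaffold` turns that signal into
joins:

1. **Filter** — keep properly paired, non-duplicate, non-supplementary
   alignments with MAPQ > 10, and barcodes supported by ≥ 50 reads.
2. **Mask** — union the spans of low-MAPQ (≤ 10) alignments, merging
   intervals closer than 40 bp, plus N runs: a repeat/ambiguity mask.
3. **Nodes** — grow a window inward from each scaffold end until it holds
   `E` = 10,000 unmasked bases (capped at `o` = 50,000 bp); scaffolds
   shorter than `m` = 5,000 bp are skipped. Each node collects the
   barcodes whose trusted reads land unmasked inside its window. Nodes
   with outlier barcode counts (upper `D` = 0.985 quantile) are removed.
4. **Score** — for an ordered node pair, the shared fraction
   |A ∩ B| / |A|; a normal distribution fitted per node over its
   shared-fraction sample converts an observation into a link score,
   −log10 of the upper-tail probability. A pair's score is the mean of
   its two ordered scores; the global threshold is calibrated as the
   99th percentile of scores among pairs sharing exactly one barcode.
5. **Layout & consensus** — accept edges greedily in descending score
   (each scaffold end used once, no cycles), then concatenate each chain
   with 100 N spacers, reverse-complementing reverse-oriented members.

The package also provides read-cloud statistics (cloud demarcation in
5 kb windows, length/density/physical-coverage estimates), contiguity
statistics (N50/N10/N90/NG50), a split-and-reclassify calibration harness
that measures type 1 (false join) and type 2 (missed join) error rates,
and a seeded simulator of the whole data-generating process for testing.

## Worked example

Simulate a 500 kb genome shattered into ten shuffled, randomly oriented
50 kb pieces, then rescaffold it:

```sh
cloudscaffold simulate --genome-length 500000 --piece-length 50000 \
    --seed 4 --out-dir demo
cloudscaffold scaffold --alignments demo/reads.sam \
    --fasta demo/draft.fasta --out-dir demo/scaffolded
cloudscaffold stats --fasta demo/scaffolded/scaffolds.fasta \
    --genome-size 500000
```

Log lines (stderr, JSON) and the final report:

```
{"stage": "ingest", "raw_records": 177559, "after_alignment_filter": 108356,
 "retained_barcodes": 470, "after_barcode_filter": 107497, "masked_bases": 245335}
{"stage": "scaffold", "n_scaffolds": 10, "n_nodes": 20, ... "n_joins": 9, ...}
{
  "max_length": 500900,
  "n50": 500900,
  ...
  "n_elements": 1
}
```

All nine true joins are recovered: the ten pieces come back as one
scaffold whose length is the original 500,000 bp plus 9 × 100 N spacers.
`demo/scaffolded/joins.agp.tsv` records component order, orientation and
gaps; `edges.tsv` records every candidate link with its shared count,
fractions and score.

Other subcommands: `cloudstats` (cloud demarcation report), `mask`
(stand-alone mask construction), `calibrate` (split large scaffolds into
50 kb children, rescaffold, classify joins, report error rates).

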