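# nucleograv

Downstream statistics for time-resolved transcriptome responses, built for
studies that ask **where** differential expression happens in the nucleus and
**how** it evolves over a time course — for example, cells responding to
hypergravity, heat shock, or routine centrifugation.

The package takes pre-computed DESeq2-style differential-expression tables
(optionally as three parallel quantifications: *regular* = all reads,
*spliced* = mature transcripts, *unspliced* = nascent transcripts), a gene
annotation, and a 3D chromatin bead-model ensemble (e.g. Chrom3D output),
and computes:

* **3D radial distribution** — for the up- and downregulated gene sets, the
  mean distance to the nuclear center over the model ensemble, against the
  expectation under random gene drawing. The headline value is the radial
  deviation Δr = r̄(actual) − r̄(expected), in µm; negative means a shift
  toward the nuclear center.
* **Coherence** — for two DEG sets A, B of the same direction on a shared
  universe of N tested genes, with |A| ≤ |B|:
  `coherence = (|A ∩ B| / |A|) / (|B| / N)`.
  Random overlap gives 1, strong coherence ≫ 1, inverted coherence ≈ 0.
* **Transition flows** — 3×3 tabulation of per-gene state changes
  (up/down/ns) between consecutive comparisons (Sankey-diagram numbers).
* **Persistent DEGs** — genes with FDR-adjusted p < α and a constant
  fold-change sign across every comparison, with paired t tests of their
  log2 fold changes against a reference time point (BH-corrected).
* **Chromosomal distribution** — per-chromosome observed vs expected DEG
  counts under uniform drawing (expected = genome-wide DEG rate × detected
  genes on the chromosome), Fisher's exact tests for the total count and for
  the up/down skew, BH-FDR star marks, and Spearman correlations between
  expected and observed counts.
* **Splice discordance** — genes upregulated on the unspliced track while
  downregulated on the spliced track, and the fraction of them also
  differentially expressed on the regular track.
* **Biotype aggregation** — transcript counts summed per biotype
  (protein-coding, retained intron, nonsense-mediated decay, ...), Student's
  t tests of each group against a control with four-level star codes, and
  per-gene biotype composition.

A gene is called differentially expressed at FDR-adjusted p < 0.05 with no
fold-change cutoff by default; both thresholds are configurable everywhere.

A **synthetic-data generator** produces every input with controllable
planted structure (radial shifts, chromosomal skew, temporal persistence,
discordant genes, biotype shifts), so the whole pipeline is testable and
calibratable without any sequencing data. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Generate a synthetic data set with planted structure (radial shifts of
−0.4 µm for upregulated and +0.4 µm for downregulated genes, upregulation
skewed onto chr16–chr22) and analyse it:

```sh
nucleograv simulate --out demo --seed 42
nucleograv radial --de demo/de_regular_hypg3.tsv \
    --annotation demo/genes.gtf --beads demo/beads.tsv
```

```
direction  n_genes  expected_mean_um  actual_mean_um  deviation_um  defined
up         3001     3.9135            3.5007          -0.4128       True
down       3442     3.9135            4.2974          +0.3839       True
```

Upregulated genes sit 0.41 µm closer to the nuclear center than random
drawing predicts and downregulated genes 0.38 µm further out — the planted
±0.4 µm shifts, recovered from the bead models alone. Coherence against the
earliest time point:

```sh
nucleograv coherence --tables demo/de_regular_hypg20s.tsv \
    --tables demo/de_regular_hypg3.tsv --tables demo/de_regular_hypg60.tsv \
    --reference de_regular_hypg20s
```

```
comparison        reference         direction  coherence  percent
de_regular_hypg3  de_regular_hypg20s  up       3.45       51.6
de_regular_hypg3  de_regular_hypg20s  down     2.51       43.0
de_regular_hypg60 de_regular_hypg20s  up       2.11       39.0
de_regular_hypg60 de_regular_hypg20s  down     1.75       28.7
```

Values well above 1 show that DEG labels persist far beyond random overlap,
decaying with temporal distance — the generator's persistence probability at
work. `nucleograv run --simdir demo --out reports` executes every statistic
and writes the full report bundle (summary table, flows, persistent genes,
discordance, per-chromosome tables, run manifest).

The same subcommands accept real data: DESeq2 result TSVs, a GTF or BED
annotation, bead models as a flat TSV or a directory of Chrom3D CMM XML
files, and transcript count matrices with transcript→gene / transcript→
biotype maps.

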