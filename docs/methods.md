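# Methods

## Radial distribution of DEG sets over a bead-model ensemble

A nucleus model represents chromatin as beads, each covering a genomic span
(a TAD or an inter-TAD region) and possibly carrying several genes. An
ensemble holds N independent 3D configurations over one shared scaffold —
alternative conformations satisfying the same contact and lamina
constraints. The nuclear radius defaults to 5 µm; all coordinates are
handled internally in µm.

**Gene → bead assignment.** Each gene maps to the bead whose genomic span
contains the gene's midpoint. Spans are half-open, so a midpoint on a
boundary belongs to the bead starting there; ties are impossible by
construction and the result is independent of annotation order. Genes whose
midpoint falls in no bead are reported unmapped, never silently dropped.
Genes in inter-TAD beads are treated exactly like genes in TAD beads. A
gene's position is its bead's center; no within-bead placement is attempted
(the data have bead resolution).

**Expected distribution.** Under the null hypothesis DEG labels are drawn
uniformly from all mapped genes, so the expected mean radial distance of a
DEG set is the per-model mean bead radius over *every* mapped gene (a bead
with k genes enters k times), averaged over models. It does not depend on
the drawn set's size or direction, so up- and downregulated sets share one
expectation (asserted to 1e-12 in the tests). The expected cumulative curve
is n_genes times the empirical CDF of all mapped genes' radii. Because every
model contributes the same gene count, pooling radii across models and
averaging per-model CDFs are algebraically identical; we therefore expose a
single estimator.

**Actual distribution.** Per model, the mean bead radius of the DEG genes;
the ensemble value is the unweighted average of per-model means ("per-model
statistic, then average"). The reported radial deviation is actual −
expected (µm); negative = shifted toward the nuclear center. An empty DEG
set (after dropping unmapped members, whose count is logged) yields an
undefined, NaN-flagged result — blank report cells, never 0.

**Bead-model I/O.** Two formats: a flat TSV dialect (model_id, chrom,
start, end, x_um, y_um, z_um, is_lad) and Chrom3D-style CMM XML (one file
per model, `<marker>` elements with x/y/z and an id encoding
chrom:start-end). CMM files written by this package declare `units="um"`
and round-trip exactly; files without a unit declaration are treated as
arbitrary units and rescaled so the outermost bead lies at the nuclear
radius, since optimizer output units vary.

## DEG classification

up ⇔ padj < α ∧ log2FC > +c; down ⇔ padj < α ∧ log2FC < −c; otherwise ns.
Defaults α = 0.05, c = 0 (no fold-change cutoff); inequalities strict;
missing padj is never significant. The tested-gene universe is the set of
table rows (detected genes), not the whole annotation. The package consumes
pre-computed DE tables and never re-runs differential testing.

## Coherence

For same-direction DEG sets A, B with |A| ≤ |B| on a shared universe of N
genes: actual = |A∩B|/|A|, expected = |B|/N, coherence = actual/expected.
The statistic is symmetric in its arguments; ties in size resolve to the
first argument. The shared universe is the intersection of the two
comparisons' tested genes — the only set on which both labellings exist.
An empty smaller set leaves the value undefined (blank), matching how such
cells are reported rather than coding them 0. The overlap fraction itself
(actual × 100) is exposed as `percent` since both normalisations are in
use; a cross-direction variant (up-in-A vs down-in-B) is available as a
diagnostic for inverted responses.

## Persistent DEGs and fold-change tests

Persistent genes satisfy padj < α with a strictly constant log2FC sign in
every comparison. Their fold changes are compared to a reference comparison
with a t test **paired by gene** — the same genes appear in every column, so
pairing is the natural reading; an unpaired variant is available by flag.
p-values are BH-adjusted across the non-reference comparisons; stars at
padj < 0.05 (*) and < 0.01 (**).

## Chromosomal distribution

Expected DEG count per chromosome = (total DEGs / total detected genes) ×
detected genes on the chromosome; expected down-share among a chromosome's
DEGs = the genome-wide down-share. Two Fisher's exact test families per
chromosome — total count ([DEG on c, non-DEG on c; DEG elsewhere, non-DEG
elsewhere]) and up/down skew ([up on c, down on c; up elsewhere, down
elsewhere]) — each BH-adjusted across chromosomes separately. Stars default
to padj < 0.05 (*) and < 0.01 (**); the second threshold is configurable
because both 0.01 and 0.02 conventions appear in practice. A binomial test
alternative is available by flag. Global agreement between expectation and
observation is summarised by Spearman rank correlations (chosen over
Pearson: the claim is about ordering, and ranks are robust to the heavy
right tail of per-chromosome counts).

Fisher's exact test is conservative: being an exact conditional test on a
discrete support, its achieved type-I rate sits *below* the nominal level
(measured ≈ 0.045 at α = 0.05 under uniform random DEG placement on a
20k-gene genome — see the calibration tests). The suite asserts the
one-sided validity property (never anti-conservative); a two-sided band
centred exactly on 0.05 is not attainable by any exact conditional test.

## Biotype aggregation

Transcript counts are summed per (biotype, sample); the top-k biotypes by
total count are retained (default 5). No internal normalisation is applied
— the analysis compares summed counts per sample, so inputs should be
comparable across samples (e.g. depth-normalised upstream). Each treatment
group is tested against the control per biotype with a Student's t test
(equal variances by default, Welch by flag), BH-adjusted **across groups
within each biotype** — the smallest defensible family — with four-level
stars (0.05/0.01/0.001/0.0001). Per-gene composition reports one gene's
transcript counts summed by biotype and as fractions of the gene total.

The spin-down exposure fraction, 100 × stop_time / exposure_time, bounds
how much of a centrifugation run the deceleration phase represents. The
total spin time is used as the denominator; adding the stop time to the
denominator changes the result only in the second decimal (e.g. 8.34 s
against 300 s gives 2.78%, against 308.34 s gives 2.70%).

## Synthetic data generator

The generator emulates the full input stack at a scale that runs in seconds
on one CPU: 24 chromosomes with human-like length ratios (small gene-dense
chr16–chr22 included), ~3,000 beads, ~20,000 genes, 100 models by default
(5,000 models reproduce production scale), an 8-comparison time course with
per-comparison DEG counts matching a real hypergravity study's regular
track, and 6 samples per group for counts.

**Bead placement.** Each bead draws a persistent radial preference u once
per scaffold from Beta(3 + bias·is_LAD, 1) — bias 0 is exactly the
uniform-in-sphere radial law (density 3u²), positive bias pushes LAD beads
outward — and per model its radius jitters around R·u (Beta, concentration
30, ≈ 0.45 µm per-model spread), with an isotropic direction. The
persistent preference is essential, not cosmetic: in a constraint-based
model ensemble each bead has a reproducible radial tendency, and that is
what makes ensemble-averaged radial statistics informative. If positions
were instead redrawn independently per model, every non-LAD gene's
ensemble-mean radius would collapse to the same value (spread ∝
1/√n_models) and no gene set of realistic size could sit 0.4 µm off the
expectation — planted shifts would be unrecoverable in principle.

**DEG labels.** Up-labels are drawn without replacement with probabilities
exponentially tilted in the gene's ensemble-mean radius; the tilt strength
is adapted (bisection on the weighted mean, then feedback) and candidate
label sets are rejected until the realized deviation is within a tolerance
(0.02 µm) of the planted δ_up. Down-labels are tilted outward analogously.
Because the ensemble-averaged actual mean of a set is exactly the mean of
its genes' ensemble-mean radii, the planted δ is recoverable by
construction. Chromosomal skew enters as an odds multiplier on the chosen
chromosomes for up-labels. Labels carry to the next comparison with
probability ρ (default 0.5); a designated persistent set (default 214 up /
87 down) is forced into every comparison, and — when ρ < 1 — any other gene
that would accidentally keep one sign throughout is demoted in the last
comparison so the planted persistent sets are recovered exactly. At ρ = 1
full persistence is the requested behaviour and no demotion occurs.

**Tracks.** Spliced/unspliced tables derive from the regular labels by
direction-preserving subsampling (unspliced keeps more up-labels, spliced
more down-labels), plus a per-comparison quota of planted discordant genes
set to unspliced-up ∧ spliced-down. Since derivation never flips a
direction, the discordant set equals the planted one exactly.

**Statistics columns.** padj is drawn uniform below 0.05 for labelled genes
and uniform in [0.05, 1] otherwise — the label ↔ threshold correspondence is
exact by construction; log2FC signs follow the labels. p-values and
baseMean are synthesized for format fidelity only. Counts are negative
binomial (dispersion 0.1, mean scaled per biotype so protein-coding
dominates total counts ~90%) with multiplicative per-group shifts on chosen
biotypes. Everything is deterministic given the config seed, with separate
seed streams for models, labels and counts.

**What the generator does not emulate.** Correlated expression between
neighbouring genes, realistic p-value/fold-change joint distributions
(labels are planted, not tested), contact-driven chromosome territories,
library-level artifacts. Passing tests demonstrate that the statistics
recover planted structure under these idealised conditions, not that real
data meet the statistics' assumptions.

## Numerical choices and degenerate inputs

* BH adjustment passes NaNs through without counting them in the family.
* Constant vectors make rank correlations undefined (NaN, logged), as do
  empty DEG sets for radial/coherence statistics — undefined is always
  distinguished from zero.
* t tests of identical samples return t = 0, p = 1 rather than NaN.
* Bead containment is validated with a 1e-6 relative tolerance on the
  nuclear radius; CDFs are evaluated on a 256-point radius grid.
* Report ordering is deterministic (karyotype order for chromosomes,
  input order for comparisons), making reruns byte-identical.

## Problem sizes used by the test suite

Unit tests run on a 5-chromosome, ~1,200-gene, 20-model configuration; the
recovery checks run the full default scale (24 chromosomes, ~20k genes,
100 models, 8 comparisons); the chromosome-test calibration simulates 1,000
uniform tables of 2,000 DEGs. These sizes were chosen so the whole suite
completes in a few minutes on one CPU while keeping every statistic in its
asymptotically relevant regime.

## Known limitations

* Radial statistics work at bead resolution; genes within a bead are
  indistinguishable.
* The uniform-drawing chromosome expectation ignores gene-length and
  expression-level biases in DE detectability.
* Fisher's conservativeness (above) means per-chromosome stars are slightly
  under-powered near the threshold.
* Biotype group tests treat summed counts as approximately normal within
  groups; with very few samples per group the t test is fragile.
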