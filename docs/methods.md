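# Methods

## Model

`svpath` treats SV pathogenicity scoring as binary classification between a
disease cohort (label 1) and a benign/control cohort (label 0), on the
assumption that the genomic/epigenomic context of pathogenic SVs differs
from that of benign SVs. Not every disease-cohort SV is pathogenic; the
labeling is deliberately noisy, and the score is calibrated only in the
sense that a variant scoring near 1 is very unlike the benign set. The
score is therefore a cohort-membership probability, not an endophenotypic
effect size.

All coordinates are 0-based half-open (BED convention); VCF input (1-based
POS, END) is converted at the boundary. Strand is ignored throughout.

### Features

Default layout: 22 features — 10 binned signal features (H3K27ac, H3K4me1,
H3K4me3, H3K36me3, H3K27me3, GC content, replication timing, CTCF, WGBS
methylation, PhyloP) and 12 annotation overlap fractions (coding, 5′UTR,
3′UTR, splice site, promoter, TAD boundary, heterochromatin, fragile site,
SINE, ultra-conserved, sensitive region, cancer gene). The layout is
config-driven, not hard-coded: any named set of tracks and interval sets
works, and the "truncated model" experiments (dropping length,
conservation, or cancer-gene features) are realized purely by editing the
feature configuration.

Binned signal: the interval is partitioned into consecutive 10-bp bins and
the feature is the mean of per-bin totals. Two deliberate choices:

* When the length is not a multiple of the bin width, the final short bin
  is kept with its raw (unscaled) sum rather than discarded or rescaled.
  Any systematic bin-count effect cancels under Z-normalization, because
  the null intervals share the SV's exact length.
* Per-bin aggregation defaults to the bin **sum** (so the feature is ≈ 10×
  the per-base mean on full bins); `bin_agg="mean"` gives per-bin means
  instead. The scale factor is irrelevant after Z-normalization.

Annotation overlap uses the union ("collapsed") intervals of each set, so
each base counts once regardless of transcript multiplicity. A chromosome
absent from an annotation set contributes 0, not an error. Signal tracks
are run-length encoded with value 0 on unreported bases, making every
query a total function; queries are evaluated with prefix sums, which is
what makes the shuffle null affordable (all n null intervals of an SV are
evaluated in one vectorized pass).

### Shuffle null and Z-normalization

Each SV gets n = 1000 (tests use 100–200) randomized intervals with the
same length and chromosome, starts uniform over `[0, chrom_len − sv_len]`,
independent, with no exclusion zones — null intervals may overlap each
other and the original SV (the simplest faithful reading of uniform
placement; no gap/blacklist masking is applied anywhere). Each raw cell is
standardized by its null mean and sd. Choices:

* Null sd uses the population (÷n) convention; at n = 1000 the distinction
  from ÷(n−1) is negligible. Configurable via `ddof`.
* σ = 0 (constant null, e.g. a constant track) maps to z = 0, consistent
  with the zero-imputation of cohort-absent features: no evidence of
  difference scores 0.
* Missingness is declared per (cohort, feature dataset), not per cell: a
  feature is missing when its underlying dataset is unavailable for that
  cohort; such cells are imputed to 0 in the Z matrix.
* SV length is appended raw, not Z-scored — Z-scoring length against a
  length-matched null is degenerate (σ = 0), and the point of the column
  is precisely to let the model up-weight extreme lengths.

The key calibration property, exploited by the tests: when an SV is itself
placed by the same uniform process as its null, z is a standardized draw
from its own null distribution, so for features built from Gaussian track
segments z is pivotal — identically distributed regardless of SV length.
This is what removes length confounding. For annotation fractions over
very short SVs the z distribution is pivotal in mean and sd but not in
shape (discreteness), which is why the calibration test asserts shape
indistinguishability on the signal features.

### Balancing, ensemble, evaluation

Controls are subsampled without replacement to the disease cohort size
before null generation and normalization (configurable). The classifier is
10 random forests, each trained on a disjoint ~10% slice of the corpus;
slices are stratified by class (the corpus is balanced, but stratification
prevents degenerate single-class slices at small n). In-corpus scores
average the 9 out-of-slice forests; external scores average all 10 (the
out-of-slice rule has no meaning off-corpus). Per-slice forests are seeded
independently per slice index, so altering one slice's rows changes only
that slice's model.

Hyperparameters (tree depth 2–10, forest size 10–5000, minimum samples to
split 10–100) are tuned by random search — a full grid with 5000-tree
forests is not desk-scale, and only ranges are meaningful — scored by
internal CV auROC on a stratified 70% tuning split, leaving 30% untouched
for holdout evaluation. "Minimum leaves to split an internal node" is
exposed as scikit-learn's `min_samples_split`; the phrasing conflates two
forest controls and this is the documented choice. Accuracy is reported
three ways, separately: stratified ten-fold CV (fresh ensemble per fold),
the 30% holdout, and the out-of-slice scores of the production ensemble
(the ensemble's own internal cross-validation). auROC uses midrank tie
handling, auPR step-wise (non-interpolated) integration; both are
cross-checked in the tests against brute-force pairwise-concordance and
step-integration oracles, exhaustively on all ≤ 12-point label patterns.

Score thresholds: pathogenic ≥ 0.9, benign ≤ 0.2, intermediate otherwise.

Feature importance is permutation importance: mean drop in out-of-slice
auROC when a column is shuffled, averaged over repetitions. Note the
standard caveat that redundant informative features mask one another — a
feature can carry signal yet show ~0 importance if correlated features
absorb it.

### Downstream analyses

* Conservation: per-SV per-base mean of the conservation track; groups are
  compared with a one-sided Mann-Whitney rank-sum test (pathogenic >
  benign).
* Gene enrichment: per gene, the fraction of its bases covered by the
  union of the SV group; the null re-places every SV in the group
  uniformly on its own chromosome with its own length, 1000 times, and
  the enrichment is the Z-score of the observed fraction under the
  permutation moments. Chromosome preservation mirrors the feature nulls
  (an interpretation: "permuted across the genome" does not pin this
  down, and internal consistency with the shuffle module was preferred).
  Genes on chromosomes without SVs, or with a degenerate (sd = 0) null,
  get an undefined Z, reported as NaN. Lengths are sorted within each
  chromosome before placement so results are exactly invariant to the
  ordering of the input group.

## Synthetic data

The fixture generator emulates a disease-vs-control contrast on a small
genome (default 3 chromosomes, 4.5 Mb total, so full pipeline runs finish
in minutes): run-length tracks with Gaussian segment values (200-bp
segments, sd 0.5, per-track means in 1.5–3.0, truncated at 0 — the
truncation is negligible at these means, keeping the Z pivotality exact),
uniformly placed annotation intervals, and cohorts with log-uniform length
distributions (≥ 51 bp so everything passes the > 50 bp filter). Planted
structure: a configurable shift (in noise-sd units) added to designated
tracks under disease SV footprints, and/or extra annotation intervals
overlapping disease SVs with a configurable probability. Planting modifies
the tracks rather than moving SVs to high-signal regions, so SV placement
stays uniform and the shuffle null remains correct by construction.

What the fixtures do **not** emulate: real chromosome lengths, assembly
gaps, GC/mappability structure, spatial autocorrelation of real epigenomic
tracks, SV clustering/recurrence, or label noise (every disease SV carries
planted signal, unlike real cohorts where most disease-cohort SVs are
passengers). Passing the recovery tests therefore demonstrates that the
machinery is correct and calibrated, not that any particular accuracy will
transfer to real cohorts.

## Problem sizes and numerical choices

Tests and examples use 100–200 shuffles (the pipeline default is 1000),
cohorts of 150–500 per class, and forests of 40–200 trees; these sizes
were chosen so the statistical assertions (chance bands, KS calibration,
recovery thresholds) have comfortable margins at desk scale. All
randomness flows from a single master seed through fixed `SeedSequence`
fan-out (per-stage, then per-slice), making every artifact bit-for-bit
reproducible; identical config + seed reproduces the score table
byte-identically. Degenerate inputs are defined rather than erroneous
wherever a convention exists (σ = 0 → z = 0; empty annotation chromosome
→ overlap 0; forced shuffle placement when the SV spans its chromosome).

## Limitations

Deletions and duplications only — no inversions, translocations, or
complex events; no SV calling, breakpoint refinement, genotyping, or
liftover; no GC/mappability-matched or blacklist-aware shuffling; no
probability calibration of the ensemble output; pathway/ontology
enrichment of the overlapping-gene list is delegated to external tools.
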