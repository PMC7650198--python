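# svpath

Pathogenicity scoring for structural variants (SVs).

Large deletions and duplications (> 50 bp) reshape the genome far more than
point mutations, yet most variant-prioritization tools ignore them. `svpath`
scores an SV by how different its genomic and epigenomic context is from
that of benign population variants: the score is the probability that the
variant belongs to a disease cohort rather than a benign/control set — a
disease classifier, not a direct effect size. It is aimed at researchers
with cohort-scale SV call sets (somatic or germline) who want a ranked list
of candidate pathogenic deletions/duplications plus the standard follow-up
analyses (conservation contrast, gene-overlap enrichment).

## Method

For an SV `[a, b)` on chromosome *c*, two feature families are computed:

* **Binned signal features** `F̄_t` for each track *t* (histone marks, GC
  content, replication timing, CTCF, methylation, PhyloP conservation):
  the interval is split into 10-bp bins, the per-base signal is summed
  within each bin, and the feature is the mean of the per-bin totals.
* **Annotation overlap fractions** `F_A` for each interval set *A* (coding,
  UTRs, splice sites, promoters, TAD boundaries, heterochromatin, fragile
  sites, SINEs, ultra-conserved and sensitive regions, cancer genes): the
  fraction of the SV's bases covered by the union of *A*.

Disease and control cohorts usually have very different SV length
distributions, which leaks into every feature. Each cell is therefore
standardized against a per-SV null: *n* = 1000 shuffled intervals with the
same length on the same chromosome, placed uniformly at random, giving

    z = (F − μ_null) / σ_null        (z := 0 when σ_null = 0)

Features whose underlying dataset is unavailable for a cohort are imputed
to 0 (no difference from the null). SV length in bp is then appended as an
explicit, unnormalized column so that extremely large events can still be
up-weighted. After balancing class sizes by subsampling controls, the
Z-matrix trains a **disjoint-slice forest ensemble**: 10 random forests,
each fit on a disjoint 10% of the rows; every in-corpus SV is scored by
the mean class-1 probability of the 9 forests that never saw it, and
external SVs by the mean of all 10. Scores ≥ 0.9 are grouped as
pathogenic and ≤ 0.2 as benign for the downstream analyses
(rank-sum conservation contrast, 1000-permutation gene-enrichment
Z-scores).

## Worked example

Generate a synthetic cohort pair (150 disease vs 200 control SVs; five of
the ten signal tracks elevated by 1.5 noise-sd under disease SV
footprints) and run the full pipeline:

```python
import json
from svpath import FixtureSpec, generate_fixture, write_fixture
from svpath.pipeline import fixture_run_config, run_pipeline

spec = FixtureSpec(n_disease=150, n_control=200, seed=42, planted_signal_shift=1.5)
write_fixture(generate_fixture(spec), "demo/fixture")
cfg = fixture_run_config("demo/fixture", "demo/run", seed=7, n_shuffles=200,
                         n_trees=200, cv_folds=10, n_permutations=500)
summary = run_pipeline(cfg)
print(json.dumps(summary["evaluation"], indent=2, sort_keys=True))
```

which logs the stage sequence and prints (abridged):

```
svpath INFO balanced to 150 per class
svpath INFO feature matrix: 300 rows x 23 columns
svpath INFO cv auROC 0.971 / holdout auROC 0.932
{
  "cv_mean_auroc": 0.9706666666666667,
  "cv_mean_aupr": 0.9583301736389972,
  "holdout_auroc": 0.9318518518518518,
  "holdout_aupr": 0.905791546975436,
  "oof_auroc": 0.9655555555555555,
  ...
}
```

The planted 1.5-sd shift is recovered: ten-fold cross-validated auROC is
0.97 and the untouched 30% holdout gives 0.93 (chance is 0.5; the same
pipeline on an unplanted fixture stays in the 0.45–0.55 band). The output
directory contains the raw and Z-normalized matrices (`*_matrix.tsv`), the
per-SV score table (`scores.tsv`: disease SVs average score 0.76, controls
0.23 in this run), the serialized ensemble, and `evaluation.json`. The
same run is available from a shell:

```bash
svpath fixture --out demo/fixture --seed 42 --signal-shift 1.5 \
    --n-disease 150 --n-control 200
svpath run --config demo/config.yaml --seed 7
```

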