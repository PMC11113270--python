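# Methods

## The problem

Genome-wide maps of single-strand DNA breaks (SSBs) and abasic (AP) sites can
now be produced at single-nucleotide resolution from bulk DNA. `breakclock`
implements the downstream analysis that turns such maps into age (and tissue)
predictors: per-gene lesion densities, univariate gene ranking, and a
repeated random-split model-evaluation harness, together with a synthetic
data generator that makes the whole chain testable without sequencing data.

## Lesion densities (LPKM) and expression (TPM)

A lesion map is a deduplicated set of `(chrom, position, strand)` records;
identity is the position, not the read, so the same position detected on both
strands counts twice and repeated detections of one position count once.
For gene *i* and sample *j*,

```
LPKM_ij = R_ij * scale / (L_i * N_j)
```

where `R_ij` is the number of lesion positions (either strand, pooled)
falling in the gene's territory, `L_i` the territory length in bp, and `N_j`
the sample's genome-wide total of lesion positions. The territory is either
the exon union (`region_mode="exon"`) or the whole gene span including
introns (`"whole_gene"`). The default `scale = 1e9` gives the value an exact
"per kilobase of territory, per million total positions" reading
(10^3 × 10^6). The scale is exposed (`--lpkm-scale`) because conventions
differ; any fixed positive scale is rank-preserving, so gene ranking, gene
sets, and model AUCs are unaffected by the choice. `N_j` counts all records
in the sample's map, not only gene-mapped ones. A lesion inside several
overlapping genes' territories counts for each of them (synthetic genes are
non-overlapping, so the distinction only matters for real annotations).

Expression is summarized as naive gene-level TPM with exon-union effective
length: `rate = count / L`, scaled so each sample sums to 10^6. There is no
isoform-level EM and no fragment-length correction; for gene-level aging
analyses this is the standard desk approximation.

Before any selection, genes are filtered on the fraction of samples with a
nonzero value: 0.40 for TPM, 0.20 for the sparser LPKM metrics, computed
across all samples pooled.

## Gene screening and ranking

*Spearman screen.* Each gene's values are correlated with age in months
(numeric, mid-rank Spearman; two-sided p from the t approximation). Genes
with p < α (default 0.05) are labelled positive or negative by the sign of
ρ; constant genes get p = 1 and sign `none`. No multiple-testing correction
is applied — the screen's output of interest is the *fraction* of flagged
genes, which under the null is calibrated at α (a property the tests check).
Per-tissue correlation ranges (max − min of per-tissue ρ across tissues)
quantify how tissue-dependent a gene's age association is; metrics are
compared on these ranges by one-way ANOVA with Tukey HSD adjustment
(scipy). Genes constant within a tissue contribute ρ = 0 there rather than
being dropped, keeping gene universes identical across metrics.

*ANOVA F ranking.* The F-score is classic one-way ANOVA across label groups
(age groups treated categorically, or tissues):
`MSB = Σ n_j (x̄_j − x̄̄)² / (c−1)`, `MSE = SSE / (n−c)`, `F = MSB/MSE`.
The implementation is written out explicitly (and verified in the tests
against scipy's independent `f_oneway` to 1e-9 relative tolerance).
Degenerate cases need a total order for ranking: `MSE = 0` with distinct
group means gives `F = +inf` (a perfectly separating gene outranks every
finite score); a constant gene gives `F = 0`, with constancy judged against
a scale-relative tolerance because group means of identical floats can carry
rounding fuzz. Ranks are 1 = largest F with ties broken by ascending gene
id, so rankings are reproducible across runs and platforms. The same
computation is available as a scikit-learn transformer
(`AnovaFScoreSelector(k)`) for use in pipelines.

Nested top-k gene sets default to sizes 15, 25, 50, 75, 100, 150, 200, 300,
400, 500 (only a few of these sizes are canonical; the schedule is
configurable), with an "all genes" set appended by the evaluation grid.
Pairwise overlap of top gene sets is tested with the hypergeometric upper
tail — the natural null for drawing two fixed-size sets from a common
universe.

## Model evaluation

Ten model families are supported: logistic regression, random forest,
Gaussian naive Bayes, LightGBM, XGBoost, AdaBoost, LASSO, elastic net, and
decision-tree regressor/classifier. Library defaults are used (no
hyperparameter search); only seeds and bounded iteration counts are set.
The three regression-style families are wrapped by an adapter that fits the
regressor on numeric class values, scores a prediction against class k as
`−|prediction − value_k|` (row-softmaxed into normalized scores), and
predicts the nearest class with ties to the lower class. GaussianNB gets an
absolute variance floor of 1e-9 per feature because constant features inside
a small training split otherwise produce degenerate likelihoods.

Each evaluation draws `n_iterations` (default 100) independent 80/20
train/test splits from a seeded generator, refits the model each time, and
scores the held-out samples with four metrics:

- **AUC** — one-vs-rest, macro-averaged over classes present in the test
  fold with at least one negative (absent classes are skipped and logged);
- **F1** — macro over argmax predictions;
- **MAE** and **Spearman** — on encoded labels. The default encoding is the
  class index 0..K−1 (an MAE of 0.04 on a five-class age problem is only
  interpretable on an index scale); months encoding is available for the
  age target. A constant prediction vector has undefined rank correlation
  and is scored 0.

Splits are stratified by class by default, which guarantees every class on
both sides; plain random splitting is available, with degenerate draws
(a class missing from either side) redrawn up to 100 times. Per-iteration
seeds are spawned from the master seed, so the entire grid is bit-for-bit
reproducible from `(seed, config, inputs)`.

*Feature selection placement.* `selection_mode="full_data"` ranks genes on
all samples before splitting — the select-then-split protocol whose
optimism on null data is itself a property this package measures —
and `"within_train"` re-ranks inside every training split, the leakage-free
alternative. Both are first-class; on data with no planted signal the
full-data mode reaches near-perfect apparent AUC while within-train stays at
chance, which is the clearest argument for reporting both.

The grid evaluator crosses metrics × nested gene sets × methods and flags
each (method, metric) pair as Tier I (mean AUC peaks at the largest nested
gene set) or Tier II (interior peak); the all-genes set is excluded from
tier assignment. A fixed gene list (e.g. DNA-damage-response genes) can be
compared against size-matched random expressed gene sets; the comparison
t-tests the fixed list's per-iteration AUCs against the pooled per-iteration
AUCs of the random sets (two-sided). Metric-vs-metric comparisons use the
standard two-sample two-tailed t-test on per-iteration AUC vectors, with
p = 1 for identical degenerate inputs.

## The synthetic generator

The generator emulates the statistical structure of a multi-tissue mouse
aging study: ages {3, 12, 19, 22, 24} months × 6 tissues × 3 replicates,
with the oldest group at 2 replicates and one brain sample dropped (a QC
exclusion analogue), i.e. 83 samples. Per gene and sample,

```
R_gj ~ Poisson( lesion_depth * share_gj ),
share_gj ∝ L_g * u_g * exp( s_g * β * a_j + γ * [tissue_j = marker tissue of g] )
```

with `a_j` the min-max-scaled age in [0, 1], `u_g` a lognormal per-gene
baseline (σ = 0.5), `s_g ∈ {+1, −1, 0}`, and shares normalized per sample so
raw totals are exactly Poisson(`lesion_depth`). Positions are placed
uniformly in the gene's exon union with a random strand, sampled with
replacement and then deduplicated; the duplicate count is kept on each map
(≈0.7% at the default depth). Expression counts are negative binomial
(gamma-Poisson, dispersion 0.1) with the same planted effect structure and
their own baselines.

Defaults: 2,000 genes (exonic length 2–8 kb, 1–5 exons), 65 positively and
35 negatively age-correlated genes (≈35% negative, matching the observation
that a large minority of damage-age correlations are negative), 60 tissue
markers (10 per tissue), β = 1.0, lesion depth 2×10^5 positions per sample,
expression depth 2×10^6 reads. The tissue effect defaults to γ = 2.0
(≈7.4-fold marker enrichment): tissue-restricted genes in real expression
atlases are typically ≥10-fold specific, and tissue identity in such data is
near-perfectly classifiable — the regime the generator is meant to emulate.

What the generator does **not** emulate: sequence context and damage
hotspots, chromatin or GC/mappability covariates, overlapping genes,
isoform structure, intronic lesion placement beyond the whole-gene span
mode, and between-animal correlation beyond independent sampling. Passing
tests therefore demonstrate that the pipeline's statistics behave correctly
under the assumed generative model, not that real breakome data carries this
much signal.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open; GTF (1-based inclusive) is
  converted at the boundary and back on writing.
- Exon sets are union-merged; adjacent intervals are fused.
- Feature matrices are written as TSV with `%.17g` floats and read back with
  round-trip float parsing, so `read(write(x))` is bit-exact.
- An empty lesion map is valid as data but rejected as an LPKM denominator,
  naming the offending sample.
- Chromosome matching is exact string equality (no "chr" aliasing).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; derived seeds stay below 2^31.

## Problem sizes

The packaged tests and the acceptance script run the study-scale design
(2,000 genes, 83 samples) with 100 split iterations for the null-calibration
and leakage analyses, 50 for the planted-signal age models, and 20 per
method family for the ten-method tissue comparison — sizes at which the
measured quantities (calibration fractions, AUC ordering, recovery rates)
are stable to well within the tolerances asserted.

## Known limitations

- Naive TPM is not RSEM; absolute expression values differ from
  isoform-aware quantification, though gene ranking is broadly similar.
- The regression→classifier adapter makes AUC comparable across all ten
  families, but reporting AUC for regression models is convention-dependent;
  treat cross-family AUC gaps involving the regression families with care.
- With ~17 test samples per split, per-iteration metrics are coarse
  (AUC granularity ~0.01); aggregate means over iterations are the stable
  quantities.
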