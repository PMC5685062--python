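# Methods

## Pipeline model and assumptions

The package detects *pathway cross-talk*: unordered pathway pairs whose
joint per-sample activity pattern separates two phenotype groups. The unit
of inference is the pair, not the pathway, and the evidence is
classification performance under resampling rather than a parametric test.
The pipeline assumes:

- expression is gene-level and already log2-scale (probe summarisation and
  normalisation happen upstream);
- two groups, each with at least two samples in every training and test
  portion of every split;
- approximately Gaussian within-group noise on the log2 scale per gene —
  this is what both the moderated t-test and the simulator use.

## Differential expression

The moderated t-statistic shrinks per-gene pooled variances `s2_g` (with
`d = n1 + n2 - 2` df) towards a prior `s02` with `d0` df; `(d0, s02)` are
estimated by matching the mean and variance of `log s2_g` to a scaled
log-F distribution (digamma/trigamma moments, trigamma inverse solved by
bracketed root-finding to 1e-12). Edge cases:

- **Excess dispersion ≤ 0.** When the spread of `log s2_g` does not exceed
  the chi-square sampling floor `trigamma(d/2)`, the hierarchical model
  would need `d0 = inf`; the prior is then a point mass at the *geometric
  mean* of the variances. This makes a constant-variance ensemble an exact
  fixed point of the shrinkage (posterior = observed variance for every
  gene). In the regular branch the implementation agrees with the
  Bioconductor limma `eBayes` reference to < 1e-9 in p-values (checked in
  the test suite via an `Rscript` oracle).
- **`prior_df = 0`** disables shrinkage and reproduces the ordinary
  pooled-variance t-test to 1e-12 — useful for comparison.
- Zero variances are excluded from hyperparameter estimation but still
  receive a shrunken posterior; an all-zero-variance matrix is an error.

The log2 fold change is case minus control. DEGs satisfy both
`|log2FC| > 1` and BH FDR `< 0.05`; both cut-offs are configurable.
BH adjustment is delegated to `statsmodels.multipletests("fdr_bh")` and is
property-tested against a brute-force step-up oracle.

## Enrichment

One-sided over-representation only: the upper hypergeometric tail
`P(X >= x)` with background `N` = genes in the analysed matrix, pathway
size `K` = members in the background, `n` = DEG count and `x` = overlap
(via `scipy.stats.hypergeom.sf`, exact to 1e-12 against rational
enumeration for all `N <= 60`). Pathways with no background overlap are
untestable and dropped before BH, so the multiplicity burden counts only
tested sets. Selection uses the double threshold raw `p < 0.01` *and*
FDR `< 0.05`. The background choice matters: a pathway catalogue's own
internal background is generally unknowable, so the matrix gene universe
is used throughout.

## Pair features and discriminating score

A pathway's per-sample activity is the mean log2 expression over its
*representative genes* — by default its members that are DEGs (fallback:
all members present in the matrix, `restrict_to_degs=False`). Restricting
to DEGs means two pathways sharing the same single DEG get identical
activities and a difference feature that is identically zero; such pairs
are kept (their DS is 0) and logged.

The discriminating score of a pair is the signal-to-noise statistic on the
per-sample activity difference `f`:

    DS = |mean_case(f) - mean_control(f)| / (sd_case(f) + sd_control(f))

with `ddof=1` standard deviations. DS is invariant under pair swap, group
relabelling and global rescaling of the matrix. When both group SDs vanish
the ratio is 0/0: DS is defined as 0 for equal means and a sentinel (1e6,
with a warning) otherwise — a degenerate exact separation that should be
inspected, not silently ranked.

Note the DS sees only the *difference* of activities: a pair whose two
pathways shift the same way between groups carries no DS signal even
though each pathway individually discriminates. The classifier stage is
deliberately given both activity columns, so it detects such co-moving
pairs; the DS highlights antagonistic (relative-activity) cross-talk.

## Classifier ranking

Per pair, a random forest (defaults: `ntree=500` trees,
`mtry = floor(sqrt(p))` features per split; `p=2` activity columns, so
`mtry=1`; a `feature_mode="diff"` switch gives the single difference
column) is evaluated by stratified k-fold cross-validation (default
`k=10`). The AUC is computed once on the pooled out-of-fold
case-probabilities — at 32 samples a per-fold AUC would rest on ~2
samples and is far noisier. When `k` exceeds the minority-class count the
fold count is lowered to it with a warning; fewer than two possible folds
is an error the driver records as a degenerate iteration. The forest is
scikit-learn's `RandomForestClassifier` used purely as configuration
(bootstrap resampling + random feature subsetting); tie handling in the
AUC is the Mann-Whitney 1/2 convention.

## Monte Carlo loop

Defaults: 50 iterations, stratified 60/40 split (per-group train size
`round_half_up(0.6 * n_group)`, so 16+16 samples give 10+10 train, 6+6
test), top-10 pairs per iteration, final report keeps pairs occurring in
at least 3 iterations. Only the training portion reaches DEG calling,
enrichment, representative-gene choice, DS and CV-AUC ranking; the test
portion is used once per top pair for a hold-out validation AUC (a test
asserts this leakage guard). Iterations that degenerate statistically —
no DEGs, fewer than two usable pathways, unbuildable folds, a single-class
test portion — are recorded with their reason and skipped, not resampled:
the run keeps exactly `n_iterations` draws and an honest occurrence
denominator. Zero successful iterations is a run-level error.

Determinism: iteration seeds are `master_seed + index`; all further
randomness (split, per-pair forests) derives from them through
`numpy.random.SeedSequence`. Two runs with one master seed write
byte-identical reports.

## Synthetic data

`simulate_study` emulates the target study design: two balanced groups
(default 16+16), `n_genes=2000` genes with baselines uniform on log2
intensities 6–12, i.i.d. Gaussian noise `sigma=0.5` per gene (optional
lognormal per-gene sigma jitter), 20 pathways of 15–40 members sampled
with overlap from the gene universe, and 20 differentially expressed genes
drawn from the two planted pathways' members, shifted by `delta=4` in
cases with equiprobable random sign (half up, half down, exercising the
absolute-value side of the DEG filter). The default effect size is large
relative to the noise so that planted-pair recovery is a sharp, nearly
deterministic property at desk-scale sample sizes; calibration properties
(type-I error, p-value uniformity, null AUC) use `effect_size=0`.

`opposing_planted_signs=True` plants the first pathway up and the second
down — the antagonistic pattern whose activity *difference* discriminates,
which is the condition under which the planted pair tops the DS ranking.
Under the default random signs the two planted pathways frequently co-move
and the DS of their pair is legitimately small, while the two-column
classifier still recovers them.

What the simulator does **not** model: batch effects, probe-level
artifacts, correlated gene-gene noise within pathways, heavy-tailed
intensities and library-size effects. Passing tests therefore demonstrate
correctness of the algorithmic chain under its own statistical
assumptions, not robustness to real-array pathologies.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the loop at reduced size —
10 Monte Carlo iterations and 100-tree forests (the calibration study uses
200 noise pairs at n=32) — which keeps the full suite in the
ten-minute range on one CPU while leaving every statistical property
sharp; the package defaults remain 50 iterations and 500 trees.

## Bundled reference tables

`crosstalk_mccv.reference` ships two small TSVs from a published
ankylosing-spondylitis cohort analysis (GSE25101: 16 active AS patients vs
16 controls): its reported DEG statistics (19 genes with log2FC and FDR)
and its final pathway-pair occurrence list (10 pairs). They are fixed
inputs for bookkeeping operations — re-applying the DEG filter, counting a
pathway's partners — not outputs of this package's pipeline. Gene symbols
were cleaned of typesetting artifacts (trailing superscript digits). The
published enrichment FDR values are not used anywhere: they depend on an
unknown proprietary background and cannot be recomputed.

## Known limitations

- Pathway activity is an unweighted mean over representative genes; no
  single-sample GSEA-style rank statistic is offered.
- The enrichment background is the expression matrix's gene universe;
  results shift with upstream filtering of that universe.
- With very few DEGs the representative-gene restriction can make many
  pathway pairs share features, producing ties that are broken
  lexicographically for determinism.
- Occurrence aggregation counts top-k membership only; it does not weight
  by rank or AUC margin.
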