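# crosstalk-mccv

Pathway *cross-talk* discovery from two-group gene-expression data: a Monte
Carlo cross-validated pipeline that ranks **pairs of pathways** by how well
their joint per-sample activity separates cases from controls.

Most gene-set analyses treat pathways as independent. Diseases such as
ankylosing spondylitis, however, are better described by interacting
pathways — an abnormality in one pathway perturbs others. This package
quantifies pairwise pathway interaction from a gene-level log2 expression
matrix (e.g. a preprocessed microarray or RNA-seq cohort) and a pathway
gene-set collection (GMT), with no dependence on any proprietary pathway
catalogue.

## The method

Each Monte Carlo iteration (default 50) draws a stratified 60/40
train/test split and, on the training portion only:

1. **Differential expression** — empirical-Bayes moderated *t* (Smyth
   2004): per-gene pooled variances *s²_g* with *d* residual df are shrunk
   towards a prior *s₀²* with *d₀* df estimated by moment-matching
   log *s²_g* to a scaled log-F; the statistic
   *t̃_g = log2FC_g / (s̃_g √(1/n₁+1/n₂))* with
   *s̃²_g = (d₀s₀² + d s²_g)/(d₀+d)* is referred to *t*(d₀+d).
   DEGs: |log2FC| > 1 and Benjamini–Hochberg FDR < 0.05.
2. **Pathway enrichment** — one-sided hypergeometric (Fisher exact) test of
   DEG over-representation in each pathway against the matrix's gene
   background; pathways kept at raw *p* < 0.01 and BH FDR < 0.05.
3. **Pair features and discriminating score** — per sample, a pathway's
   *activity* is the mean log2 expression of its DEG members; for every
   unordered pathway pair (A, B) the difference *f_s = act_A(s) − act_B(s)*
   gives the signal-to-noise discriminating score
   *DS = |M₁ − M₂| / (SD₁ + SD₂)* between groups.
4. **Random-forest ranking** — per pair, a forest (ntree = 500,
   mtry = ⌊√p⌋) on the two activity columns is scored by stratified
   10-fold cross-validated AUC (pooled out-of-fold probabilities); the
   top 10 pairs are validated on the held-out 40%.

Pairs appearing in ≥ 3 of the iterations' top-10 lists enter the final
report with their occurrence counts and mean CV / validation AUCs.

A synthetic-data module simulates the whole study design — balanced
groups, log2-normal expression, DEGs planted inside designated pathways —
so every stage is testable against a known ground truth.

## Worked example

```python
from crosstalk_mccv import (
    MCCVConfig, RFConfig, SimulationConfig, run_mccv, simulate_study,
)

# 16+16 samples, 2,000 genes, 20 pathways; 20 genes shifted by |log2FC|=4
# inside the planted pair (PW001, PW002)
expr, labels, sets, truth = simulate_study(SimulationConfig(seed=1))
config = MCCVConfig(n_iterations=10, master_seed=1, rf=RFConfig(ntree=100))
run = run_mccv(expr, labels, sets, config)
print(run.report.sorted_rows().to_string(index=False))
print("ok iterations:", run.n_ok, "| best pair:", run.best_pair())
```

prints

```
pathway_a pathway_b  occurrence_count  mean_cv_auc  mean_validation_auc
    PW001     PW002                10        0.962             0.965278
ok iterations: 10 | best pair: ('PW001', 'PW002')
```

The planted pair is the only pair recurring across iterations: it entered
the top-10 list of all 10 iterations, with a mean cross-validated AUC of
0.962 on the training portions and 0.965 on the held-out samples — the
pipeline recovers the known cross-talk and nothing else.

The same analysis runs from the shell:

```sh
crosstalk-mccv simulate --out-dir study/ --seed 1
crosstalk-mccv run --expression study/expression.tsv --labels study/labels.tsv \
    --gmt study/pathways.gmt --out-dir results/ --seed 1 --iterations 10
crosstalk-mccv report results/report.tsv --pathway PW001
```

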