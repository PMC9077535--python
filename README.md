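# omicforest

Label-free proteomics experiments routinely leave a large fraction of the
protein × sample intensity matrix unquantified: low-abundance proteins drop
below the detection limit, often in whole replicate blocks at a time.
`omicforest` predicts — and imputes — those missing protein intensities from
the transcriptomic context measured in the same samples: mRNA expression
(TPM) of the protein's transcripts, the expression of miRNAs targeting those
transcripts, the expression of circRNAs that sponge those miRNAs, and static
protein/transcript annotation (length, mass, amino-acid composition, GC
content, stability measurements).

It is aimed at computational proteomics groups who have paired
RNA-seq/miRNA-seq/circRNA and label-free MS data and want either (a) a
leakage-honest estimate of how predictable protein abundance is from RNA
features, or (b) a model-based alternative to statistical imputation of
missing intensities.

## The method

One observation is a (protein *p*, sample *s*) pair. Because one protein maps
to several transcripts, each transcript to several targeting miRNAs
(miRNA–target-interaction score in [0,100]; "stringent" keeps score ≥ 80,
"all" keeps everything), and each miRNA to several sponging circRNAs (only
links with > 7 binding sites count), every multi-valued quantity is collapsed
with six summary statistics — mean, median, min, max, sum, sd — on both the
raw and the log₂(x+1) scale. The default schema has **196 raw features**:

| category | n |
|---|---|
| linear-transcript expression | 12 |
| miRNA expression (stringent + all) | 24 |
| transcript characteristics | 36 |
| protein characteristics | 48 |
| MTI scores | 12 |
| sequencing depth | 1 |
| circRNA sponging scores | 6 |
| circRNA expression | 12 |
| protein stability | 45 |

The target is log₂ intensity. Preprocessing follows the classic caret
contracts in a fixed order: dummy encoding → near-zero-variance filter
(freqRatio > 95/5 **and** percentUnique < 10%, both strict) → greedy removal
of correlated predictors (|r| > 0.75, target excluded first) → centering and
scaling → complete-case filtering. Every statistic is learned on training
rows only.

Evaluation is group-aware: the 80/20 hold-out and the 10-fold CV assign
whole *samples* or whole *proteins* to one side, never splitting a group.
The contrast between the two strategies is the scientific point — held-out
samples of known proteins are far easier than never-seen proteins, because a
protein-identity intercept dominates intensity variance. R² is the squared
Pearson correlation between predictions and observations. Recursive feature
elimination ranks features per CV fold by model importance, refits nested
subsets, and aggregates ranks across folds; random forests (500 trees, mtry
tuned over {2, ⌊√p⌋, p−1}) are the default of an eight-learner roster
(`rf, kknn, glmnet, lm, cubist, bag, bstTree, blackboost`).

Because real paired multi-omics data cannot ship with the package, a
synthetic generator produces bundles with the same linkage structure and a
known generative model (`log₂I = α_p + β·log₂(mRNA+1) − γ·miRNA burden +
noise`, with α_p correlated to the protein's linear density and
abundance-dependent missingness), so every claim is testable against ground
truth.

## Worked example

```bash
omicforest run-all --out demo_run --seed 7
```

or from Python, on a small synthetic experiment:

```python
from omicforest import RunConfig, SynthConfig, run_pipeline

config = RunConfig(outdir="demo_run",
                   synth=SynthConfig(n_proteins=80, n_samples=12, seed=0),
                   hyperparameters={"mtry": "sqrt", "n_estimators": 200},
                   seed=7)
manifest = run_pipeline(config)
```

which prints/records (abridged):

```json
{"raw_features": 196,
 "features_after_dummy_encoding": 203,
 "features_after_nzv_filter": 197,
 "features_after_correlation_filter": 96,
 "train_rows_after_complete_case": 469}
{"algorithm": "rf",
 "train_rmse": 0.239,
 "test": {"rmse": 0.733, "r_squared": 0.913, "pct_change_vs_train": 206.4}}
```

Reading: the three categorical annotation columns expand to 10 indicators
(196 → 203); six near-zero-variance columns (constant organism, rare
indicator levels, degenerate sd summaries) are removed; the correlation
filter removes another 101 — amino-acid counts correlate with mass and
length, and duplicate-scale summaries correlate with each other — leaving 96
predictors. Under a by-sample split the forest explains ~91% of held-out
log₂-intensity variance (RMSE 0.73); the +206% RMSE change from train to
test is the usual random-forest in-bag optimism. Switching
`strategy="by_protein"` drops R² dramatically — that gap, not the absolute
number, is the finding to look at.

The CLI exposes each stage separately (`simulate`, `assemble`, `preprocess`,
`evaluate`, `train`, `predict`, `go-eval`, `impute`); see `omicforest
--help`.

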