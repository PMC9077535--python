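# Methods

## The prediction problem

`omicforest` treats label-free protein quantification as a supervised
regression problem: the target is the log₂ of a protein's Hi3-style
intensity in one sample, and the predictors are everything the
transcriptome and the annotation databases know about that protein in that
sample. Modeling on the log₂ scale makes the residuals roughly homoscedastic
across the ~5 orders of magnitude that intensities span and makes RMSE
interpretable as a fold-change error (RMSE 1.0 ≈ a 2-fold typical error).
R² is reported as the squared Pearson correlation between predictions and
observations. This is deliberate: it measures ranking/association and is
insensitive to a constant bias, unlike 1 − SS_res/SS_tot; the two diverge
for biased predictors (a prediction shifted by a constant has R² = 1 but
nonzero RMSE), so both metrics are always reported together.

## Feature construction

The mapping protein → transcripts → miRNAs → circRNAs is many-to-many at
every hop, so each multi-valued quantity is summarized six ways (mean,
median, min, max, sum, sd) rather than privileging one summary. Choices that
needed making:

- **Singleton sd = 0, not missing.** R's `sd()` of a single value is `NA`;
  propagating that would make the complete-case filter delete every
  single-transcript protein (roughly half of them). Zero is the
  information-preserving choice; the cost is that `*_sd` columns become
  strongly zero-inflated and are often (correctly) removed by the
  near-zero-variance filter.
- **log₂ uses a pseudocount of 1** (`log2p(x) = log₂(x+1)`): TPM zeros are
  common and log₂(0) is undefined. The log₂ block summarizes *transformed
  values* (Σ log₂(xᵢ+1)), never the transform of a summary.
- **Stringent vs all miRNA regimes**: an interaction is stringent when its
  score is ≥ 80 (inclusive boundary); circRNA–miRNA links count only with
  strictly more than 7 binding sites. miRNA *expression* summaries
  de-duplicate miRNAs across a protein's transcripts (set semantics); MTI
  *score* summaries aggregate at the edge level, because the score belongs
  to the (transcript, miRNA) pair, not to the miRNA.
- **Linkage is per-protein and sample-constant**; only expression varies by
  sample. A protein with no stringent miRNA (or no eligible circRNA) gets
  missing values in that block and drops out of model-ready rows at the
  complete-case step — a real attrition mechanism, not an artifact.
- **Protein characteristics (48)**: length, mass, 20 amino-acid counts, 20
  proportions, linear density (mass/length), three categorical annotation
  fields, plus log₂ variants of mass and linear density to fill the
  48-column category. **Stability (45)**: nine opaque measurements, each
  carried with replicate values and summarized by five statistics (sd
  omitted in this block to keep the category at 9 × 5).
- **Strand is coded ±1** so its summaries are meaningful (mean = strand
  balance, sd = mixture indicator).

## Preprocessing semantics

The filters re-implement the classic caret contracts and are checked
against `caret::nearZeroVar` as an independent oracle in the test suite:

- `nzv`: freqRatio = modal count / second-modal count (∞ for constants),
  percentUnique = 100 · distinct/n. Flag iff zero-variance, or freqRatio
  **strictly** > 95/5 and percentUnique **strictly** < 10. (Current caret
  releases print freqRatio 0 for constant columns; the classic convention
  of ∞ is kept here. Flags agree either way.)
- `find_correlated`: greedy — repeatedly take the pair with the highest
  |r| above 0.75 and drop the member with the larger mean absolute
  correlation to the remaining columns; ties drop the earlier column in
  manifest order (deterministic). Post-condition (tested exhaustively): no
  surviving pair exceeds the cutoff. The target is excluded before
  filtering, otherwise the most predictive features would be removed.
- Centering/scaling uses the sample sd (n−1 denominator, the R
  convention), so `[1,2,3]` standardizes to `[−1, 0, 1]`.
- Order is fixed — dummies → NZV → correlation → center/scale →
  complete-case — and is part of the contract; permuting it changes the
  result. All statistics are learned on training rows and re-applied
  verbatim to test rows; a test verifies that corrupting test data leaves
  the learned transform untouched.

## Splitting and evaluation

Group hold-out assigns whole samples (or whole proteins) to train or test;
the number of training groups is `round(0.8 · n_groups)` with banker's
rounding. Group 10-fold CV deals shuffled groups round-robin, so fold sizes
differ by at most one group. Disjointness is asserted at run time on every
split. RFE ranks features once per fold from the full model's native
importance (impurity importance for forests), refits nested subsets at each
requested size, and averages: the optimal size is the argmin of mean CV
RMSE (smaller size wins ties) and the aggregated ranking is the mean
per-fold rank with alphabetical tie-breaks.

The learner roster maps to scikit-learn: RandomForestRegressor (`rf`, 500
trees; when mtry is unset it is tuned over {2, ⌊√p⌋, p−1} by inner 3-fold
CV RMSE), KNeighborsRegressor (`kknn`), ElasticNet (`glmnet`),
LinearRegression (`lm`), BaggingRegressor over trees (`bag`),
GradientBoostingRegressor (`bstTree`), HistGradientBoostingRegressor
(`blackboost`), and ExtraTreesRegressor standing in for the rule-based
committee learner (`cubist`), which has no Python implementation. Inside
RFE, and in most experiments shipped here, mtry is pinned to ⌊√p⌋: tuning
it per fold-and-subset multiplies the fit count ninefold for a metric
change well inside fold noise. Feature importance for reporting is
permutation importance (seeded, repeats = 5, negatives clipped to 0);
nearest-neighbour models have none and are directed to the RFE ranking.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes — it
is the package's test bed, not a simulator of sequencing reads or spectra.

- **Expression** is log-normal per entity with a per-sample log-deviation
  (mRNA location/scale 1.5/1.5 nats, within-sample sd 0.4; miRNA 2.5/1.2/0.3;
  circRNA 0.8/1.0/0.3), truncated to 0 below a detection floor of 0.25 —
  most entities are not constitutively expressed.
- **Linkage**: 1 + Poisson(0.8) transcripts per protein; Poisson(5) target
  miRNAs per transcript with Uniform(0,100) scores; Poisson(4) circRNA
  links per circRNA with 1 + Poisson(6) binding sites. These densities give
  most — not all — proteins a stringent miRNA set and an eligible circRNA,
  so complete-case attrition is realistic.
- **Protein identity**: log₂ intensity is
  `α_p + 0.8·log₂(mean mRNA TPM + 1) − 0.2·Σ log₂(stringent miRNA TPM + 1)
  + N(0, 0.5)`, with `α_p` of sd 2 drawn with correlation 0.6 to the
  protein's linear density. The intercept is the mechanism behind the
  by-sample vs by-protein gap: a by-sample model can learn α_p from the
  protein's near-unique annotation fingerprint, a by-protein model can only
  recover the fraction that density explains. Amino-acid counts are
  multinomial draws from human-background frequencies and mass is the exact
  residue-mass sum, so linear density is a genuine physicochemical quantity.
- **Missingness** is abundance-dependent: P(missing) is logistic in the
  standardized log₂ intensity (slope 1.2), with the intercept calibrated by
  bisection so the expected missing fraction equals `missing_rate`
  (default 0.3). Optionally, masking decisions are made per
  (protein, timepoint) block — samples sit in timepoint groups of 3
  replicates — so replicates go missing together, as they do around the
  detection limit. The mechanism is a modeling choice; nothing forces real
  dropout to be logistic.
- Defaults are 200 proteins × 20 samples. What the generator does *not*
  emulate: sequence-based miRNA targeting, batch or isobaric/compositional
  effects, shared transcripts between proteins, correlated noise across
  proteins. Passing tests therefore demonstrate correctness of the
  machinery and the *direction* of the split effect, not real-data effect
  sizes.

## Imputation and GO stratification

Imputation retrains the forest on all in-scope rows with observed targets
and complete features, then predicts missing cells only for proteins with
at least one observed in-scope value — a never-observed protein has no
anchor and stays missing. Observed intensities pass through bit-identical
(asserted), and tree-ensemble predictions are asserted to stay inside the
training target range (forests cannot extrapolate; this is also why the
approach suits absolute-intensity data better than compositional data).
The imputation report flags values outside each protein's observed range ±
a tolerance in log₂ units. GO stratification takes a flat protein→term
table (no ontology up-propagation), drops terms with fewer than 10
predicted proteins, and ranks terms by correlation-form R²; proteins
contribute to every term that annotates them.

## Problem sizes and numerical choices

Shipped experiments use sizes that keep the full test suite around a
minute of CPU: the default 200 × 20 bundle (~4000 rows, ~1500 model-ready
training rows) for the split-gap and imputation studies; 400 rows × 50
features × 10 folds × 10 replicate seeds for the RFE
planted-feature-recovery study (120-tree forests); 50 random matrices for
the correlation-filter post-condition. The acceptance script averages the
split gap over three replicate splits because a single by-protein test set
holds only ~40 proteins and its R² is accordingly noisy. All randomness
flows from explicit seeds; a run seed fans out to per-stage seeds through a
seeded integer draw, and equal seeds reproduce results bit for bit.

## Known limitations

- The correlation filter is O(p²) per step and Pearson-only; no robust or
  rank-based option.
- `evaluate` defines R² = 0 when predictions are constant (correlation is
  undefined there); this is a reporting convention, not a statistical claim.
- The 80/20 split can be slightly off 80% for small group counts because
  groups are atomic.
- Feature-level missingness is never imputed — only the target is — by
  design: rows with missing features are excluded (training) or left
  missing (imputation) and logged.
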