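# Methods

## Problem and model

liqbio classifies plasma samples from a multi-analyte blood test. The input
is a feature table with 39 protein-biomarker concentrations, an omega score
summarizing cfDNA mutation evidence, and clinical covariates (age, sex,
race); labels are Normal or one of seven cancer types (esophageal and
gastric cancers are merged into a single upper-GI class, as is conventional
for this panel). Two tasks are solved with the same stage recipe: cancer
detection (Cancer vs. Normal on the full cohort) and cancer typing (an
ordered cascade of one-vs-rest binary stages over the cancer samples).

### Omega score

`Ω = Σᵢ wᵢ ln(pᵢᶜ/pᵢᴺ)` over sequencing wells, with `wᵢ` the well's share of
unique identifier (UID) molecule counts. The natural logarithm is used. How
the per-well p-values are derived from mutant-allele-frequency distributions
is upstream of this package; they are consumed as given, and the score is
invariant to rescaling all UID counts. p-values must lie in (0, 1]; zero or
negative values are rejected rather than clamped.

### Feature reduction

Pearson correlations are computed on the training split only, with
pairwise-complete observations; constant features yield undefined (NaN)
entries rather than exceptions. Pairs with `|r| > 0.5` (strict) are
redundant. Pairs are processed in `|r|`-descending order (ties broken
lexicographically); if neither member has been dropped yet, the member with
lower mutual information with the class label is dropped. The skip rule
makes correlation chains deterministic; dropping is invariant to input
column order. MI ties keep the earlier canonical column.

MI is a binned plug-in estimate in nats via `I = H(X) − H(X|Y)`. Features
with more than `n_bins` distinct values are discretized by equal-frequency
binning (default `n_bins = 10`); discrete features use their values
directly, so on fully discrete data the estimator is exact. Estimates are
clamped at 0 against estimation noise. A binned plug-in estimator was chosen
over k-NN estimators because it is exactly testable against the closed-form
double sum and adequate for ranking two candidates within a pair.

### Feature selection

An XGBoost classifier (binary log-loss objective, misclassification error
rate as the monitored metric) ranks features by total split gain. Default
five rounds, top-10 per round: round 1 sees all reduced features; before
each next round the `floor(n/5)` lowest-gain features are removed, giving
the 40/32/24/16/8 schedule at 40 inputs. Removing low-gain (rather than
high-gain) features between rounds is the only reading under which most
top features persist across rounds. Zero-gain features rank below all
positive-gain features; ties fall back to canonical column order, making
the whole procedure bit-reproducible under a fixed seed. The final
selection is the deduplicated union of per-round top features in first
occurrence order.

### Training and ensembling

The stage classifier is LightGBM (leaf-wise histogram gradient-boosted
trees) consumed through a fit/predict-probability contract, pinned to one
thread with deterministic row-wise histograms for bit-reproducibility.
Random search draws `n_estimators ∈ {50, 100, …, 500}`, `num_leaves` from a
50-point grid spanning 5–500, and `learning_rate` uniform on (0, 1)
excluding 0; each draw is scored by mean balanced accuracy over an inner
5-fold stratified CV of the training split (60 draws by default; smaller
values are exposed for quick runs). The winning configuration is trained
with stratified tenfold CV; each fold model keeps its held-out balanced
accuracy as its voting weight. Prediction is weighted soft voting on
positive-class probabilities — weights normalized by their sum, so scores
stay in [0, 1] and are invariant to weight rescaling — thresholded at 0.5
with the boundary rounding up. Soft voting (rather than weighted hard
votes) was chosen because it preserves an AUC-capable continuous score;
the alternative is a one-line change in `ensemble_predict`.

### Cascade

Stage 0 is detection on the full cohort. Stage *t* ≥ 1 takes the samples of
the not-yet-claimed cancer types, labels `class_order[t−1]` positive and the
rest "Other". Seven types therefore give seven stage datasets and
1 + (7 − 1) = 7 fitted stages. Each stage independently re-runs the full
split/reduce/select/tune/train chain on its own 90/10 stratified split
(per-class test counts are rounded half-away-from-zero, which maps a
1005/812 cohort to a 101/81 test set) with its own derived seed
(`seed + stage index`). The stage order is a configuration parameter; the
default follows the conventional listing (colorectal, breast, upper GI,
lung, pancreas, ovarian, liver). A sample rejected by every typing stage
receives the last class in the order — the negative side of the final
binary stage — so the decision is total. Stage splits are drawn
independently; test samples of one stage may appear in another stage's
training population, which matches per-stage reporting but means cross-stage
test metrics are not strictly nested.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
any real assay's units or reference ranges:

- **Biomarkers** are log-normal (non-negative, right-skewed): a per-feature
  baseline log-mean drawn once per cohort, log-scale SD `noise_sd`
  (default 1). Informative features get class-dependent log-scale shifts in
  SD units.
- **Correlated pairs** share a Gaussian latent factor. The latent
  correlation is calibrated analytically (inverting the bivariate
  log-normal correlation map) so the realized raw-scale Pearson r matches
  the configured target; strong negative targets are unattainable for
  log-normals and rejected. Class effects on a pair member dilute the
  pooled correlation somewhat, so tests check realized r empirically
  (±0.05). A feature may appear in at most one pair, and a pair whose
  members carry different effects for the same class is rejected as
  contradictory — this keeps the reduction step's correct answer
  well-defined.
- **Omega** is computed by the real `compute_omega` on simulated well data:
  4 wells, UID counts uniform on [50, 2000], `p_N ~ U(0,1]` and
  `p_C = v^(1+shift)` with independent `v ~ U(0,1]`. This gives the closed
  form `E[Ω] = −shift`, used as an analytic oracle; cancer samples get
  `shift = 1` by default (omega evidence present but noisy), controls 0.
- **Demographics**: ages are clipped normals matching the target cohort's
  ranges/means (controls 17–88, mean 49; cancers 22–93, mean 63); sex and
  race are categorical codes with probabilities matching the cohort's
  marginals. Default class counts are 1005 cancers over seven types and
  812 controls.

What passing on synthetic data does *not* show: robustness to real-world
batch effects, assay drift, non-log-normal marker distributions, missing
not-at-random patterns, or correlated demographic confounding. The
generator exists to verify the machinery (does reduction drop exactly the
planted redundancy? does selection recover planted markers? does the
cascade route samples correctly?), not to estimate clinical performance.

## Cost model

Only biomarker assays are charged: $2 per routine test (AFP, CA 19-9,
CA 125, CEA, Prolactin, CA 15-3), $5.5 per specialized test, 2.5 h per
assay. Clinical covariates and the omega score carry no assay cost —
the 12-biomarker detection panel pricing ($62.5, 30 h) is only consistent
with charging biomarkers exclusively. Cost and time are additive over
disjoint panels and order-invariant.

## Numerical and degenerate-input choices

- Undefined metrics (0/0 denominators) are reported as `None`, never
  coerced to 0; macro-averages skip undefined entries and use exact
  summation so they are order-invariant.
- AUC is the trapezoidal area with tied scores grouped (equal to the
  Mann–Whitney concordance with half credit for ties).
- Missing feature values stay NaN end to end; both learners handle them
  natively. No imputation.
- Categorical covariates are presented to learners as small integer codes
  (single columns, not one-hot), with the code table carried in metadata.
- Classes with fewer than 2 samples cannot be split; folds exceeding the
  smallest class size raise stratification errors.
- All randomness flows through explicit integer seeds; learners run
  single-threaded by default so reruns are byte-identical.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` fits the full seven-type cascade on a 1817-sample
synthetic cohort (39 biomarkers + omega + 3 covariates) with 30
random-search draws per stage, tenfold CV, and the 5×10 selection schedule
— sizes chosen so a complete run finishes in a few minutes on one core
while exercising every stage at the cohort's real class proportions. The
printed-input computations (metric suite on the 100/1/0/81 confusion
matrix, 101/81 split arithmetic, panel costs) are exact and
seed-independent.

## Known limitations

- The pipeline assumes the feature table is assembled upstream; no support
  for raw sequencing or mass-spec inputs.
- No probability calibration across cascade stages; stage scores are not
  comparable as posteriors.
- Random search is the only tuner; no early stopping.
- The MI estimator's binning (equal-frequency, 10 bins) is a ranking
  heuristic; it is not a consistent MI estimate for small samples.
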