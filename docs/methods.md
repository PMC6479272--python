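# Methods

`sigsurv` implements a complete analysis chain for multigene-signature
prognostic modeling in ovarian cancer: qPCR preprocessing, immune-based
patient stratification, penalized Cox survival models validated with nested
leave-one-out (LOO) cross-validated predictors, and signature-similarity
scoring. This note documents the models, the conventions chosen where the
design was genuinely open, and what the synthetic cohorts do and do not
emulate.

## Relative quantification and imputation

Expression enters the analysis as comparative-Ct relative expression:

    R(g,s) = 2^-(dCt(g,s) - dCt(g,cal)),   dCt(g,s) = Ct(g,s) - mean_h Ct(h,s)

with the arithmetic mean over the four housekeeping genes (ACTB, TOP1, UBC,
YWHAZ) on the Ct scale — identical to the geometric mean of the
housekeeping quantities on the linear scale. Amplification efficiency is
fixed at 2 per cycle (a constant, not a per-gene parameter). All modeling
happens on log2(R): the log transform tames the right-skew of relative
expression values.

Missing log2 values are completed by chained equations with predictive mean
matching (PMM): columns are initialized at their means; in each of 10
cycles every incomplete column is regressed by least squares on all other
columns, and each missing cell receives the observed value of one of the
k=5 donors whose predictions are nearest to its own prediction (donor drawn
deterministically from the seed, default 1). Imputation is single, not
multiple: one completed matrix feeds all downstream stages. Observed cells
are never modified. Imputation runs on the log2 matrix (the modeling
scale); per-column missingness must stay below 50%.

## Stratification

Gene–gene structure is summarized by Pearson correlation with two-sided
t-based p-values, Holm step-down adjusted over the unique off-diagonal
pairs.

Patients are clustered on their full 46-gene profiles with agglomerative
average linkage (UPGMA) on the uncentered-Pearson dissimilarity
d(x,y) = 1 − Σxy/(‖x‖‖y‖). Ties in the agglomeration merge the pair whose
clusters contain the smallest leaf indices (lexicographic rule) — a
documented convention so runs are reproducible; ties have probability zero
for continuous data. The tree is cut into k=3 clusters by breaking the two
largest-height merges. Clusters are ranked by mean expression over the
ten-gene immune core (the 8 immune markers plus S1PR4 and CD1B): lowest →
immune_low, highest → immune_high, remainder → mixed. If the extreme
cluster means differ by less than `min_separation` (0.5 log2 units by
default) the cohort is declared unstratified and everyone is labeled
mixed. The k=3 cut, the core gene set and the separation guard are all
configurable; they operationalize what is otherwise a visual judgement on
a heatmap.

Per-gene group comparisons are routed by Levene's test (center = mean,
α = 0.05): Student's t / one-way ANOVA with Tukey HSD under equal
variances, Welch's t / Welch ANOVA with Games–Howell otherwise; p-values
are two-sided, with Holm-adjusted values reported across genes. The design
has a single grouping factor, so the ANOVA is one-way. Categorical
associations use the Pearson chi-square without continuity correction.

## Penalized Cox engine

Ties use the Breslow approximation throughout (Efron is available for the
univariate fit behind a flag). Covariates are standardized internally to
zero mean and unit population SD (1/n); coefficients are reported per
original unit (β) and per SD (β*, the penalty scale). The engine maximizes

    l(β) − λ·P(β),   P = ½Σβj²  (ridge)   or   Σ|βj|  (lasso)

by Newton–Raphson with step halving (ridge/unpenalized) or iteratively
reweighted least squares with cyclic coordinate descent and soft
thresholding (lasso), on risk-set sums accumulated in a single pass over
the time-sorted data. Monotone likelihoods (perfect separation) are flagged
as non-convergence; no estimate is reported silently.

λ is chosen on a 100-point log-spaced grid from the all-zero bound
λ_max = max_j |∂l/∂βj(0)| down to 10⁻⁴·λ_max (the ridge grid is shifted up
by 10³, mirroring common penalized-regression practice), minimizing the
LOO cross-validated partial deviance of Verweij–van Houwelingen:

    cvl_i = l_train(β̂(−i)) − l_train−i(β̂(−i)),   dev = −2 Σ_i cvl_i .

This form remains defined for LOO folds where a single subject's partial
likelihood would be degenerate.

For speed, each leave-one-out refit is warm-started from the full-training
solution at the same λ plus the carried fold correction from the previous
λ, and iterated with a fixed Fisher metric (the Cholesky factor of the
full-training penalized Hessian, which changes only by O(1/n) per fold),
falling back to full Newton if not converged within 30 iterations. The
accelerated kernel agrees with independent per-fold full-Newton refits to
~3·10⁻⁷ relative deviance, and its λ grids, deviance argmins and nested-LOO
predictors match R's `cv.glmnet(..., nfolds = n, grouped = TRUE)` on
identical data (predictor correlation 0.9993).

The Breslow baseline cumulative hazard is evaluated with every covariate at
its sample mean. Variable importance at a 36-month horizon is
ΔS36_j = S36^exp(β*_j) − S36, the change in predicted 36-month survival for
a subject one SD above the mean on variable j alone; ranking by |β*| and by
|ΔS36| coincide.

## Validation machinery

An outer LOO loop wraps the *entire* development process: for each held-out
patient the remaining data are standardized, λ is selected by inner LOO
deviance, the model is fitted, and the patient's linear predictor η̃ is
computed on the training-fold standardization. All performance measures use
these cross-validated predictors only:

- **c-index** (Harrell): fraction of usable pairs where the higher
  predicted risk has the shorter survival; the shorter time must end in an
  event, ties between two events are unusable, tied predictions count ½.
- **PEV** (Schemper–Henderson): V = (D − D_x)/D, the relative reduction in
  time-averaged absolute prediction error of the Cox model on η̃ versus the
  marginal Kaplan–Meier; event times weighted by d_t/G(t−) with G the
  censoring-distribution Kaplan–Meier; subjects censored before t
  contribute the usual conditional mixture. Negative raw estimates are
  truncated to 0 so the reported fraction lies in [0,1]. A constant
  predictor has V = 0 exactly (its model curve is defined as the
  marginal).
- **global p**: two-sided Wald p of a univariate Cox fit on η̃ (constant
  predictors give p = 1).
- **added value**: likelihood-ratio test of the gene-derived η̃ in a
  bivariable Cox model over the clinical η̃ alone; predictors with
  |r| > 0.999 fall back to a Wald test whose (near-)singular information
  matrix correctly drives p toward 1 for exact duplicates.
- **risk groups**: quartiles of η̃ (linear-interpolation quantiles);
  strictly below Q1 = low risk, strictly above Q3 = high risk, boundary
  values intermediate; Kaplan–Meier per group with the k-group log-rank
  test.

Binary treatment-response models (penalized logistic, intercept
unpenalized, λ by the same LOO scheme with binomial deviance) are validated
with repeated stratified k-fold cross-validation (default 40×5-fold),
reporting per-repeat out-of-fold AUC and binomial deviance as mean ± SD,
plus the AUC difference to the clinics-only model.

Two properties of LOO cross-validated predictors are worth knowing, both
verified to occur identically in an independent implementation (R glmnet)
on the same data — they are properties of the validation scheme, not of
this engine:

1. *Pessimism under signal.* Each patient's prediction comes from a model
   that never saw their outcome; the self-exclusion shifts predictions
   systematically against concordance. The effect grows with the covariate
   count and shrinks with the number of events and the strength of the
   signal.
2. *Anti-conservatism of the global p under the null.* The cross-validated
   predictors of different patients are mutually dependent (any two share
   n−2 training subjects, and the per-fold penalty re-selection can jump),
   which overdisperses the naive Wald statistic of a Cox fit that treats
   η̃ as a fixed covariate. On pure-noise cohorts of n=60 with 10 genes the
   two-sided global p rejects at roughly 40% instead of 5%, and the
   inflation does not disappear by n=150. Small global p-values for
   weakly-performing models should therefore be read jointly with the
   c-index and PEV, never alone; the added-value and response-model tests,
   which compare predictors rather than testing one against zero, do not
   show this inflation in our null simulations.

## Synthetic cohorts

The generator emulates the statistical skeleton of a 173-patient advanced
ovarian cancer qPCR cohort:

- **Expression**: multivariate normal on the log2 relative-expression
  scale; genes grouped into co-expression blocks with exchangeable
  within-block correlation (immune core ρ=0.5, sphingolipid blocks
  ρ=0.4–0.5, an uncorrelated background block), per-gene noise SD 1 log2
  unit. Three planted subtypes (immune_low / mixed / immune_high at the
  observed 47/70/56 split) shift the immune core by ∓1 log2 unit and the
  sphingolipid blocks in the opposite direction (±0.6–0.8), reproducing the
  inverse sphingolipid/immune expression patterns that distinguish the
  subtypes in tumors.
- **Clinical covariates** from the cohort's marginal frequencies: age
  N(56, 11²); serous histology 88.4%; FIGO II/III/IV 4.6/80.3/15.0%
  (ordinal 0/1/2); grade 3 72.3%; peritoneal carcinomatosis 69.9%;
  residual disease none/≤1cm/>1cm 73.4/17.3/9.2% (ordinal 0/1/2).
- **Survival**: Weibull baseline (shape 1.2; OS scale 120 months, PFS
  scale 32 months) scaled by exp(η) with η the centered linear predictor of
  the true effects; administrative censoring uniform on 12–48 months,
  emulating trial-like follow-up (median ~31 months). Scales are
  calibrated to the cohort's event fractions: ~29% OS deaths and ~57% PFS
  events.
- **True effects**: protective log2-unit hazards on the genes the combined
  prognostic model ranks highest (CD68, SMPD2, SMPD1, LPAR3, CD163, CD3E;
  adverse PPAP2B, ENPP2) plus strong clinical effects (FIGO 1.1,
  residual disease 1.2, age 0.055/yr, peritoneal 0.7, grade 0.5 per-unit
  log-hazards — HRs of ~1.6–3.3, in the range reported for advanced ovarian
  cancer). Effects are sized so that the *cross-validated* performance of
  the fitted models reproduces the study-scale picture — combined-model
  nested-LOO c-index ≈ 0.75 and PEV ≈ 20% at n=200 — given the LOO
  pessimism described above.
- **Response**: Bernoulli with logit linked to immune markers (CD68, CD3E,
  MS4A1 positive; residual disease negative), intercept calibrated to
  ~73% responders, making immune-high tumors respond more often.
- **Missingness**: optional MCAR at a configurable cell-wise rate; the
  per-variable missingness of the real cohort is unknown, so MCAR is an
  assumption, not a reconstruction.

What the generator does *not* emulate: plate/batch effects, amplification
efficiency variation, non-normal expression marginals, informative
censoring, missingness that depends on expression level, and the real
cohort's exact correlation graph. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not robustness to those real-data complications.

`emit_ct_table` derives a raw Ct fixture from any complete expression
matrix (housekeeping genes at constant Ct plus a per-sample loading offset
that normalization cancels exactly), giving a round-trip identity with the
preprocessing module at 10⁻⁹.

## Numerical choices

- Newton tolerance 10⁻⁸ on the applied step for reported fits; 10⁻⁵ inside
  cross-validation (the error after an accepted step of size s is O(s²)).
- Lasso coefficients below 10⁻¹² in absolute value are flushed to exact
  zero (boundary soft-threshold ties leave ~10⁻¹⁶ dust otherwise), so the
  all-zero contract at λ ≥ λ_max holds exactly.
- Exponentials of linear predictors are capped at e⁵⁰⁰ against overflow in
  monotone-likelihood excursions; steps larger than 10 are trust-region
  capped.
- Constant covariate columns get scale 1 at standardization (their
  coefficients are identically 0 under any penalty).
- Quantiles use linear interpolation (the common "type 7" definition).

## Problem sizes in the test and acceptance batteries

The test suite runs the full nested machinery at cohort sizes chosen to
exercise the study-scale behavior within a desk-scale compute budget:
null calibration at n=60 with 10 genes over 200 replicates; signal
recovery at n=200 with the full 52-variable combined model; subtype
recovery at n=150; PEV monotonicity at n=300 over 20 seeds. The
acceptance script reports the same quantities with the replicate counts
recorded in its output (`n` fields).

## Known limitations

- Only Breslow tie handling in the penalized engine; heavy ties merit
  Efron, which is available solely for univariate fits via lifelines.
- Single imputation understates imputation uncertainty in downstream
  standard errors; the analysis consumes one completed matrix by design.
- PEV truncation at 0 discards the (rare, small) negative estimates a
  useless predictor can produce.
- The added-value test treats the two cross-validated predictors as fixed
  covariates, ignoring their estimation uncertainty — the standard framing
  for this comparison.
- The uncentered-Pearson sample clustering is sensitive to overall
  expression magnitude by construction; that is intentional (it matches
  the field's clustering convention for such heatmaps) but means profiles
  should share a common calibrator.
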