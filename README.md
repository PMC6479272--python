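# sigsurv

Multigene-signature prognostic modeling for epithelial ovarian cancer.

Advanced serous ovarian cancer lacks reliable molecular criteria for
stratifying patients into risk groups. One line of attack profiles each
tumor with a focused qPCR signature — here 38 sphingolipid/lysophosphatidate
signaling genes (enzymes of the sphingomyelin/salvage pathway, the S1P and
LPA receptor families, CD1 lipid-presentation molecules) plus 8 immune
lineage markers — and asks two questions: do the immune markers split the
cohort into *immune-low* and *immune-high* tumor subtypes, and does the
signature carry prognostic information beyond the standard
clinicopathological factors?

`sigsurv` is a tested, reusable implementation of that analysis chain for
statisticians and computational biologists working with signature-level
expression and survival data:

- **qPCR preprocessing** — comparative-Ct relative quantification
  R = 2^−ΔΔCt against the geometric housekeeping mean (ACTB, TOP1, UBC,
  YWHAZ) and a calibrator sample; log2 transform; chained-equations
  imputation with predictive mean matching.
- **Stratification** — Pearson correlation structure with Holm correction;
  uncentered-Pearson average-linkage clustering of patients; immune-core
  ranking into immune-low / mixed / immune-high; Levene-routed group
  statistics (Student/Welch t, ANOVA/Tukey, Welch-ANOVA/Games–Howell),
  chi-square, PCA.
- **Prognostic models** — univariate Cox (HR, 95% CI, Wald p) and
  ridge/LASSO-penalized Cox maximizing l(β) − λP(β) with Breslow ties,
  λ chosen by leave-one-out cross-validated partial deviance
  (Verweij–van Houwelingen); penalized logistic models for binary
  treatment response; importance as ΔS36 = S36^exp(β*) − S36, the change
  in predicted 36-month survival per +1 SD of a covariate.
- **Honest validation** — an outer leave-one-out loop around the *entire*
  development process yields cross-validated linear predictors η̃, from
  which Harrell's c-index, the Schemper–Henderson proportion of explained
  variation (PEV), a global Wald p, a likelihood-ratio added-value test
  over the clinical model, and quartile risk groups with Kaplan–Meier /
  log-rank are computed. Seven variable sets are compared: Clinics,
  Sphingo, Immune and their combinations.
- **Signature similarity** — per-gene median log2 profiles aligned by
  Pearson correlation against a conditions × genes compendium with a
  relative-similarity ranking; top-N co-expression lists and symbol-level
  overlaps.
- **Synthetic cohorts** — a generator reproducing the statistical skeleton
  of a 173-patient cohort (planted subtypes with block-correlated log2
  expression, Weibull survival under a Cox linear predictor, ~29% deaths
  under administrative censoring, subtype-linked response, MCAR
  missingness), so every downstream stage is testable without patient
  data.

## Worked example

```python
from sigsurv import (
    ModelSpec, SyntheticConfig, assign_subtypes, c_index, cox_univariate,
    generate_cohort, global_p, loocv_predictors, pev,
)

cohort = generate_cohort(SyntheticConfig(n_samples=173, seed=1))
print(f"{cohort.clinical.table['os_event'].sum()} deaths among {cohort.n} patients")

sub = assign_subtypes(cohort.expression, cohort.signature)
print(sub.labels.value_counts().to_string())

res = cox_univariate(cohort.expression.values["CD68"].to_numpy(),
                     cohort.clinical.outcome("OS"))
print(f"CD68 univariate: HR={res.hr:.3f} "
      f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}), p={res.p:.1e}")

cvp = loocv_predictors(cohort, ModelSpec("clinics+sphingo+immune", "ridge", "OS"))
out = cohort.clinical.outcome("OS")
eta = cvp.eta.to_numpy()
print(f"combined model (nested LOO): c-index={c_index(eta, out):.3f}, "
      f"PEV={100 * pev(eta, out):.2f}%, global p={global_p(eta, out):.1e}")
```

prints

```
46 deaths among 173 patients
subtype
immune_high    83
immune_low     81
mixed           9
CD68 univariate: HR=0.523 (95% CI 0.408-0.670), p=2.9e-07
combined model (nested LOO): c-index=0.847, PEV=30.20%, global p=6.4e-16
```

Reading it: the synthetic cohort reproduces the target event rate (46/173 ≈
27% deaths). Clustering on the signature separates the planted immune-low
and immune-high tumors (the generator's boundary "mixed" samples mostly
attach to the nearest extreme cluster). Higher CD68 — a macrophage marker
planted as protective — halves the hazard per log2 unit. The combined
clinical + signature ridge model, validated with fully nested leave-one-out
predictors (the held-out patient never influences standardization, penalty
tuning or fitting), discriminates strongly on this seed; across seeds the
cross-validated c-index of the combined model fluctuates around ~0.75–0.85
at this cohort size. The nested loop above takes a few minutes; the
lighter stages are instant.

The same pipeline runs from the shell:

```bash
sigsurv simulate --out cohort/ --seed 1 --n-samples 173
sigsurv evaluate --dataset cohort/ --models clinics,clinics+immune --outcome os
sigsurv run-all --out run/ --seed 1
```

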