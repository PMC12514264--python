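# Methods

This note documents the models and conventions implemented in `senescore`,
the choices made where several defensible conventions exist, and what the
synthetic-cohort validation does and does not establish.

## Normalization

Raw counts are normalized with RLE (relative log expression) median-ratio
scale factors. The reference "median library" is the per-gene geometric
mean of counts across samples; a gene with a zero count in any sample has
reference 0 and is excluded from the ratios. Each sample's raw factor is
the median of count/reference over the remaining genes **divided by the
sample's library size**, and factors are rescaled to geometric mean 1, so
that the effective library size is `lib_size × factor`. This is the
composition used by the standard DGE toolchain this field relies on, and
the implementation was verified bit-for-bit against Bioconductor edgeR
4.0.16 (`calcNormFactors(method="RLE")` + `cpm(log=TRUE, prior.count=2)`);
the frozen reference values live in `tests/test_normalization.py`. Note
the factor itself is invariant to rescaling one sample's counts (the
library size carries the scale); normalization acts entirely through the
effective library sizes.

log2-CPM uses a library-size-scaled prior: with effective libraries `L_j`
and their mean `L̄`, sample j's prior is `p_j = prior_count · L_j / L̄`
(default `prior_count = 2`) and

```
log2cpm(g, j) = log2( (count + p_j) / (L_j + 2·p_j) · 1e6 ).
```

The transform is finite at zero counts for any positive prior and strictly
increasing in the count within a sample. No low-expression gene filter is
applied by default; RLE raises a clear error when no gene is positive in
every sample (the caller is told to filter first).

## Composite scores

Each gene is z-scored across the scored samples (SD denominator n−1;
zero-variance genes are excluded and logged, never divided by zero). A
score is the unweighted mean of member-gene z-scores; the summary score
averages over the 112-gene deduplicated union of CSP/SIP/SRP — not the
mean of the three sub-scores, which would double-weight the two shared
genes. Gene matching is exact string match after whitespace stripping; no
alias resolution. The default `missing_policy="error"` refuses silently
changed score definitions; `"drop"` is opt-in and records the number of
genes actually averaged. Z-scoring is unweighted and uses whatever sample
is scored; survey weights enter only at the modeling stage.

Score columns therefore have mean exactly 0; their SD depends on the
average pairwise correlation of member genes (≈0.2–0.3 in cohorts with a
moderate latent loading, matching the descriptive scale such scores show
in real blood RNA-seq).

## The synthetic cohort

The generator emulates a population-survey blood RNA-seq study, not any
particular data set:

* **Counts**: negative binomial with variance `μ + μ²/θ` (default
  dispersion θ = 10, typical of bulk blood RNA-seq), gene baselines
  log-uniform on `exp(1.5)…exp(6)` expected counts, log-normal library
  offsets (SD 0.2 on the natural-log scale), additive gene-independent
  batch shifts (46 plates, SD 0.1), and a latent factor loading only on
  senescence-set genes (loadings uniform in `[0.5, 1.5] × 0.15` on the log
  scale).
* **Latent factor**: standardized; built as `Σ β_c z(x_c) + noise` over
  the configured covariates, so each programmed `β_c` is the population
  standardized association. Defaults: age group 0.10, female 0.04, BMI
  class 0.08, weekly drinks 0.03.
* **Outcomes**: continuous outcomes are `β·f + √(1−β²)·noise` on the
  standardized scale, rescaled to natural units (pace of aging mean 1.0 SD
  0.1, clock age acceleration SD 4 years, biological-age acceleration SD
  8.1 years added to chronological age, cognition mean 15.5 SD 4.3 rounded
  and clipped to 0–27). Multimorbidity is Binomial(5, p) and mortality
  Bernoulli with logit links in the factor (defaults 0.25 and ln 1.5
  log-odds per SD); the mortality intercept is solved numerically so the
  expected event rate equals the configured 6-year rate (default 0.162).
  Vital status is 1 = alive, 2 = presumed alive (10% of survivors),
  3/4 = deceased this/prior wave; mortality is status ∈ {3, 4}. A small
  fraction of vital status (0.7%) and a quarter of biological age are set
  missing to exercise complete-case filtering at realistic rates.
* **Weights**: gamma with mean 1 (shape 4), mildly tilted by age group so
  that weighting is consequential, not decorative.
* **Marginals** (age 4 groups, sex, race/ethnicity, education, BMI class,
  smoking pack-years, weekly drinks, insomnia, cell-type proportions) are
  drawn independently at the descriptive rates of the target population
  type; sample size defaults to 3580.

What the generator does **not** emulate: covariate dependence structure
(real age/sex/education are correlated), survey design (strata, clusters,
nonresponse), gene–gene correlation beyond the single latent factor,
count outliers, or cell-composition-driven expression shifts (the
cell-proportion columns are independent Dirichlet draws). Passing tests
therefore demonstrate correctness of the algorithms and calibration of the
inference under the assumed model, not robustness to survey-design or
compositional artifacts in real data.

The `TruthRecord` (latent factor, programmed effects, loadings, batch
shifts) is the surface for parameter-recovery tests: regressions of
outcomes on the *true* factor recover programmed effects; regressions on
the noisy composite scores are attenuated by design (score–factor
correlation ≈ 0.5–0.7 at default loadings), which is the expected
errors-in-variables behavior, not a defect.

## Association models

* **Standardized coefficients**: the continuous outcome (linear family)
  and all continuous predictors are z-scored on each model's analysis
  sample (n−1 SD); binary indicators and category dummies stay 0/1.
  Categorical references: age 55–64, non-Hispanic White, less than high
  school, not overweight/obese, first batch plate.
* **Weights**: analytic weights in WLS / binomial GLM (`var_weights`),
  with HC1 robust standard errors whenever weights are non-unit. This
  approximates design-based survey variance estimation without strata or
  clusters; point estimates satisfy exact frequency-weight equivalence.
* **Mortality models** are logistic and report odds ratios per SD of the
  standardized score. Nuisance 0/1 indicators whose active group has a
  constant outcome (e.g. a batch plate with no deaths in a reduced-scale
  cohort) quasi-separate the likelihood; they are dropped before fitting
  and recorded in `dropped_terms`, mirroring how survey software omits
  perfectly predicting dummies. Genuine separation on substantive terms,
  non-convergence and runaway coefficients (>15 absolute log-odds) raise
  errors.
* **Analysis samples** are complete cases on each model's variables;
  mortality is derived from vital status (deceased iff 3 or 4), and the
  presumed-alive sensitivity filter drops status-2 rows before the
  complete-case step.
* **Age acceleration** is the residual of biological age on chronological
  age (OLS with intercept; mean exactly 0; units years), computed on the
  subsample with non-missing biological age.
* **BH-FDR** is the step-up procedure (suffix minimum of `p·m/rank`,
  capped at 1). In the grid it is applied per predictor term across the
  five score models, and per (family, outcome) across scores for the
  outcome models' focal terms; other rows carry no adjusted p.
* **Cross-validation**: seeded k-fold (default 5), stratified on the
  outcome for logistic models, with held-out R² defined as 1 − SSE/SST
  using the held-out fold's own SST, plus RMSE and MAE; logistic metrics
  are computed on predicted probabilities against the 0/1 outcome (a
  documented convention — there is no single standard definition). The
  full-sample R² uses the same prediction-based definition.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run reduced but structurally
faithful problems: oracle agreement on 100 random count matrices and 1000
random p-vectors; score/residual centering on a 500-gene × 1000-sample
cohort; parameter recovery over 50 seeds at n = 3000 (phenotype level,
against the truth factor); type-I calibration over 500 null-grid fits at
n = 800 with all 46 plates — chosen so samples-per-parameter stays near
the full design's regime, since heteroskedasticity-robust SEs are known to
over-reject when dummy-heavy designs leave too few observations per
column; and the CV-vs-full-sample R² direction over 50 seeds at n = 500.

## Limitations

Cross-sectional by construction: nothing here supports causal claims about
senescence and outcomes. The weighted-variance approximation (HC1 rather
than full survey linearization) can differ from design-based software in
the second decimal of standard errors. The single-latent-factor count
model cannot reproduce divergent behavior between scores (e.g. one pathway
moving opposite to the others), which real cohorts do show; extending the
generator to multiple factors is straightforward but out of scope.
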