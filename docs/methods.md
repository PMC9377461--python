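# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions.

## Synthetic cohort model

The generator emulates an elderly-inpatient cohort in which falls are
covariate-driven and extend the stay additively.

* **Covariates.** One age covariate, uniform on [0, 1] (ages 65–99 rescaled
  so a unit change spans the full range, matching the odds-ratio
  convention used for such cohorts), plus `K = 48` independent Bernoulli
  covariates with prevalences staggered linearly from 5% to 50%,
  mimicking diagnosis/care-need/lab/drug flags.
* **Fall model.** `logit P(fall) = b0 + x'β`. Default `β` alternates sign
  with tapering magnitude and is scaled so that Var(x'β) = 2·Φ⁻¹(0.73)²;
  for a rare outcome with normal-ish linear predictor this puts the
  in-sample AUC of the true propensity score near 0.73, the discrimination
  typical of fall-risk propensity models on 49 administrative covariates.
  The intercept `b0` is calibrated by root-finding (Brent on [−30, 10])
  so the *expected* prevalence on the realized covariate draw equals the
  target (default 0.024); failure to bracket is a configuration error.
* **Length of stay.** Baseline stay is lognormal with marginal mean
  10.6 d and SD 6.8 d (σ² = log(1 + cv²), μ = log m − σ²/2). Confounding
  enters on the log scale: the standardized fall linear predictor
  contributes `los_confounding_sd` (default 0.25) of the total log-SD,
  with the noise SD shrunk so marginal moments are preserved. Because the
  stay-relevant covariate combination is exactly the fall linear
  predictor, matching on the propensity score is sufficient to remove the
  confounding — the cleanest setting in which the estimator should work.
  Fallen subjects receive `true_atet` extra days additively (default
  17.8 d), so the ground-truth ATET is exact by construction. Stays stay
  continuous; rounding to whole days is a reporting concern.
* **Missingness.** Per-column rates; default blocks put 19.7% on a
  lab-like block of 8 covariates and 8.3% on a drug-like block of 8,
  mirroring typical EHR patterns. MCAR masks cells independently; MAR
  makes the masking probability logistic in the always-observed age and
  fall fields (slopes 1.2 and 0.8, intercept calibrated to the column
  rate).
* **Risk scores.** Equal-variance binormal model: non-events ~ N(0, 1),
  events ~ N(δ, 1) with δ = √2·Φ⁻¹(AUC); the expected AUC equals the
  target by the standard closed form.

What the generator does *not* emulate: covariate correlation structure,
informative (MNAR) missingness, non-additive or heterogeneous treatment
effects, censoring or in-hospital death, calendar drift, or clinical-text
features. Passing tests therefore demonstrate correctness of the
estimators under the assumed data-generating process, not robustness to
every real-EHR pathology.

## Imputation

Chained equations with per-type engines: binary columns by logistic
regression with a Bernoulli posterior draw (domain closure in {0, 1});
continuous columns by linear regression with predictive mean matching,
k = 5 donors, which keeps imputations inside the observed support and is
robust to the skewed lab-style variables such cohorts impute. Columns are
visited in order of increasing missingness for `n_cycles = 10` sweeps
(single-column problems converge in one). Predictors are all other
covariates plus the fall indicator, preserving the covariate–outcome
relationship the downstream propensity model needs. `m = 20` completed
data sets by default; per-imputation seeds are spawned from the master
seed via `SeedSequence`, so runs are reproducible and imputations
independent. Parameter-uncertainty draws (Bayesian or bootstrap) are not
taken; for the marginal-bias and pooling guarantees tested here the
simple fits suffice, and only point estimates are pooled (arithmetic
mean) — no Rubin's-rules variance combination, since per-imputation
analyses are run and averaged rather than pooled at the coefficient
level.

## Propensity analysis

* Logistic fit by Newton MLE (statsmodels); rank-deficient designs are
  rejected with the offending columns named; non-finite parameters
  (separation) are an error, not a warning.
* Matching: 1:1 nearest neighbor on the score with replacement. Ties in
  distance resolve to the lowest control id, which makes the matching
  deterministic and permutation-stable. No caliper by default (exposed as
  an option).
* Standardized difference: Cohen-style d with averaged variances,
  `(m_t − m_c)/√((s_t² + s_c²)/2)`, sample variances with n−1; the same
  formula covers binary columns via p(1−p). This is the convention of the
  propensity-matching literature and reproduces published balance values
  at 2 dp. Post-matching balance counts reused controls once per use.
* ATET: mean pair difference (identical to mean treated minus mean
  matched-control outcome). CI: percentile bootstrap, default 1,000
  resamples of the matched pairs. The bootstrap conditions on the
  realized matching and ignores propensity-estimation noise; simulation
  (50 replicates at n = 30,000) shows ≥ 90% coverage of a 10-day true
  effect under the generator's conditions, which is what the test asserts.
  An Abadie–Imbens analytic variance is out of scope.

## Rosenbaum bounds

Zero differences are dropped; tied absolute differences get midranks.
T = sum of ranks of positive differences. Under hidden bias Γ the
worst-case sign probability is p⁺ = Γ/(1+Γ), giving bound moments
E⁺ = p⁺·Σr and V = p⁺(1−p⁺)·Σr². The default P value is
1 − Φ((T − E⁺)/√V) with no continuity correction — standard practice at
the scale of ~1,700 pairs; note Σr²/4 at Γ = 1 equals the classical
tie-corrected signed-rank variance. `method="exact"` evaluates the
sign-flip distribution exactly by dynamic programming over doubled
(integral) midranks, generalized to Bernoulli(p⁺) signs; it exists for
small-n work and as the exact reduction at Γ = 1, and is validated against
brute-force enumeration of all 2ⁿ sign patterns in the tests.

The minimum Hodges–Lehmann estimate is the smallest τ with
T(diffs − τ) ≤ E⁺(diffs − τ), solved by bisection to 10⁻⁶ days over
[min(diffs) − 1, max(diffs)]. The expectation-crossing criterion is used
rather than a p = 0.5 crossing because the two coincide at Γ = 1 (where
the solution is the median of Walsh averages) and the former is
numerically stable as ranks re-order during the shift. Per-imputation
bounds are averaged per Γ for the reported table.

## Classifier evaluation

AUC by midrank Mann–Whitney (equal to trapezoidal ROC area; cross-checked
against scikit-learn in tests). Youden cutoff maximizes
sensitivity + specificity − 1 over observed score values with the rule
`score ≥ cutoff → positive`; ties break toward the lowest cutoff,
favouring sensitivity — the sensible direction for fall screening.
Undefined metric ratios (zero denominators) are NaN, never silently 0.
NRI is the two-category version on class assignments, with the standard
multinomial-variance asymptotic z test; continuous NRI is not
implemented. The two-fold harness selects each fold's cutoff on the
opposite fold and averages metrics arithmetically, summing the confusion
tables for the pooled cross-table.

## Decision model

The accounting generalizes a full-prevention calculation to prevention
rate r: prevented true positives stay `L_f − A` days, unprevented true
positives remain at `L_f` in the intervention-day denominator, false
positives contribute `L_u`, savings are `r·TP·A` against a lost
opportunity `r·FN·A`. This reconstruction reproduces every internally
consistent published cell (the four-scenario table, the in-text
full-prevention figures, and the treat-all quartet to ±1 Yen). Two
published "reduced days" cells in the partial-prevention rows only
reproduce at a 25.5% rate — the rate quoted in the source's prose — while
their companion lost/net/cost cells match 25%; the package treats 25% as
normative and the tests document the 25.5% reconciliation. One published
cost cell (1769) differs from unrounded arithmetic (1768.4) by a source
rounding wobble; Yen comparisons therefore carry a ±1 tolerance.
Report rounding is half-up (days/day to 3 dp, Yen to the nearest unit);
internal arithmetic is never rounded, and `ScenarioResult` exposes the
unrounded day totals so callers can apply whole-day conventions
explicitly. Cutoff sweeps use the distinct observed scores plus a −∞
sentinel whose all-positive endpoint coincides with the treat-all
baseline.

## Pipeline and problem sizes

Stages write plain-text artifacts plus a manifest (config hash, seed,
stages); reruns under the same configuration are byte-identical, and
stages can resume from a run directory. Defaults follow the analysis
conditions above (m = 20 imputations, Γ grid 1–8, the four scenarios,
30.3/10.6 d stays at 40,000 Yen/day). Simulation-based guarantees are
checked at sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances: prevalence and AUC calibration at n = 50,000 and the
published evaluation-set size (10,386 with 228 events), estimator
coverage with 50 replicates of n = 30,000, and balance at n = 72,314 —
the scale of the motivating cohort, where ~1,700 matched pairs put the
per-covariate balance noise safely below the 0.1 criterion.

## Known limitations

* The bootstrap CI understates variance slightly when control reuse is
  heavy (many treated mapped to one control).
* MICE draws no parameter uncertainty, so between-imputation variance is
  mildly understated; only point estimates are pooled.
* The exact sign-flip distribution is O(n·Σr²) and intended for n ≲ 50.
* The decision model prices bed-days only; it ignores intervention cost
  heterogeneity, fall morbidity beyond stay length, and any behavioural
  feedback from deploying the classifier.
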