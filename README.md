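# fallstay

Causal and decision-analytic modelling of in-hospital falls among elderly
inpatients: how many extra hospital days does a fall cause, how robust is
that estimate to unobserved confounding, and what is a fall-prediction
model worth — in bed-days and Yen per day of preventive intervention?

The package is aimed at hospital epidemiologists and clinical data
scientists who have (or can only *describe*) an observational cohort of
hospitalizations with fall indicators, baseline covariates and lengths of
stay, plus optionally a risk classifier's scores. Because such EHR cohorts
are private, a synthetic-cohort generator with known ground truth is a
first-class component: every stage of the pipeline can be exercised,
validated and benchmarked offline.

## What it computes

**Extended stay caused by falls (ATET).** With fall indicator `Z`,
covariates `x` and length of stay `Y`, the propensity score
`e(x) = P(Z=1 | x)` is fit by maximum-likelihood logistic regression on the
(multiply-imputed) covariates. Each fallen case is paired with the unfallen
case of nearest `e(x)` (1:1 nearest-neighbor matching *with replacement*),
and the average treatment effect on the treated is

    ATET = mean( Y_treated − Y_matched control ),

with a percentile-bootstrap 95% CI over matched pairs and standardized-
difference balance diagnostics (|d| < 0.1 = balanced). Missing covariates
are handled by multiple imputation by chained equations (MICE, m = 20 by
default); analyses run per imputation and are averaged.

**Sensitivity to hidden bias (Rosenbaum bounds).** An unobserved covariate
may shift the within-pair odds of falling by at most Γ. For each Γ the
package reports the worst-case one-sided Wilcoxon signed-rank P value and
the minimum Hodges–Lehmann effect estimate; Γ = 1 recovers the ordinary
test and the classical HL estimate (median of Walsh averages).

**Classifier evaluation.** Midrank Mann–Whitney AUC, the Youden-index
cutoff, confusion-matrix metrics (sensitivity, specificity, precision,
F1), two-category net reclassification improvement between models, and a
two-fold cross-validation harness.

**Decision model.** A confusion matrix (TP, FP, FN, TN) plus stay/cost
parameters (mean stay of fallen cases `L_f`, of unfallen cases `L_u`,
daily bed cost) and a scenario (effect `A` days, prevention rate `r`)
yield, per day of intervention:

    D        = r·TP·(L_f − A) + (1−r)·TP·L_f + FP·L_u     (intervention days)
    reduced  = r·TP·A / D
    lost     = r·FN·A / D
    net      = reduced − lost
    cost     = net × daily_cost

plus a treat-everyone baseline and a savings curve over classifier cutoffs.

## Worked example

```python
from fallstay import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_subjects=20_000, m_imputations=5, n_cycles=3,
                     n_boot=500, seed=42)
run_pipeline(cfg, "demo_run")
```

This simulates a 20,000-hospitalization cohort (fall prevalence ~2.4%,
lognormal baseline stay with mean 10.6 d and SD 6.8 d, a true extension of
17.8 d for fallen cases, confounded covariates, block-wise missingness,
binormal risk scores at AUC 0.851), imputes, matches, and evaluates. The
run log prints one line per stage:

```
fallstay simulate: n=20000 prevalence=0.0229 seed=42
fallstay impute: m=5 cycles=3
fallstay match: atet=18.03 [17.05, 19.01] pairs=458
fallstay sensitivity: 9 gammas
fallstay evaluate: auc=0.866 cm=(366,4780,92,14762)
fallstay decide: 4 scenarios on cm=(366,4780,92,14762)
```

The matched estimate 18.03 d (95% CI 17.05–19.01) recovers the simulated
truth of 17.8 d even though the naive fallen-minus-unfallen gap is ~2 days
larger due to confounding. `demo_run/sensitivity.csv` then shows how the
estimate degrades under hidden bias — e.g. in this run the minimum
Hodges–Lehmann estimate falls from 18.07 d at Γ=1.0 to 15.24 d at Γ=2.0 —
and `demo_run/scenario_table.csv` converts the classifier's confusion
matrix into net savings (here 0.088 days/day ≈ 3531 Yen/day under a 100%
prevention assumption).

The same stages are available from the shell:

```sh
fallstay all --seed 42 --outdir demo_run
fallstay decide-from-counts            # scenario table from packaged counts
```

With the packaged published inputs — confusion matrix TP=168, FP=1638,
FN=60, TN=8520; stays 30.3/10.6 d; 40,000 Yen/day — `decide-from-counts`
prints the four-scenario table with net reductions
0.099 / 0.022 / 0.044 / 0.011 days per intervention day (about
3951 / 886 / 1768 / 420 Yen/day).

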