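# gsdpred

Predicting gait-stabilizing-device (GSD) use — canes, walkers and similar
mobility aids — from center-of-pressure traces recorded on a consumer
balance board, combined with a short questionnaire and grip strength.

Falls are the leading cause of injury in older adults, and people who would
benefit from a GSD often adopt one only after a serious fall. A cheap,
objective screen for "sways like a device user" identifies people to target
with fall-prevention interventions. This package reimplements, as a tested
pipeline over synthetic cohorts, a clinical prediction analysis built on
that idea: 30-second quiet-standing tests in four poses (eyes open/closed ×
feet apart/together, two trials each) on a Wii-Balance-Board-class force
plate, plus 25 scalar features (age, sex, 19 survey items from a modified
Vulnerable Elders Survey, 4 grip measures).

## The model

For subject *i* with scalar covariates *zᵢ* and a functional covariate
*xᵢ(t)* — the squared sway-velocity (or acceleration) magnitude
*vₓ(t)² + v_y(t)²* on a 0.1 s grid over the 30 s test — GSD use *yᵢ* follows
a Bernoulli generalized functional linear model:

```
logit P(yᵢ = 1) = γ₀ + zᵢᵀγ + ∫₀³⁰ xᵢ(t) β(t) dt
```

with the regression curve β(t) expanded in a cubic B-spline basis
(10 functions by default) and fitted by penalized IRLS. The pipeline
mirrors the full study design:

- **synthetic cohorts** (`gsdpred.synthgen`): mean-reverting Gaussian sway
  traces with a class velocity effect confined to an early time window,
  plus a roster with class-shifted ages, grips and correlated survey
  responses, exclusion flags and missingness;
- **ingestion** (`gsdpred.ingest`): exclusion filters, fixed 25-feature
  encoding, predictive-mean-matching imputation (chained equations) for
  subjects missing ≤ 4 values;
- **functional features** (`gsdpred.features`): finite-difference velocity
  and acceleration, nearest-sample resampling to the 300-point grid,
  squared magnitudes, per-trial aggregates — 20 covariates per subject;
- **models** (`gsdpred.fglm`): the functional logit above, AIC backward
  selection over the scalar features, regression curves with pointwise 95%
  bands and significant regions;
- **evaluation** (`gsdpred.evaluate`, `gsdpred.report`): 10-fold CV with
  per-fold selection, a probability-1 override for subjects unable to
  complete the tests unassisted, a pooled threshold enforcing specificity
  ≥ 0.75, AUC/accuracy/sensitivity/specificity, and a characteristics
  table with Fisher-exact / Kruskal-Wallis p-values.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort and write their tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
simulated 268 subjects (62 flagged for exclusion, 1 unable to complete)
wrote 2120 traces to results/data/traces

$ python analysis/02_ingest_cohort.py
268 consented -> removed 21 (equipment error), 39 (missing survey), 2 (missing WBB) -> 206 retained
retained cohort: 84 GSD+, 122 GSD-

$ python analysis/03_extract_features.py
built 20 covariate matrices for 206 subjects (1 unable-to-complete subjects carry empty rows)

$ python analysis/04_crossvalidate_models.py
       scope         kind  threshold  specificity  sensitivity  accuracy   auc
    EO_FA_t1     velocity        0.0        0.811        0.929     0.859 0.902
    ...
best model by AUC: EO_FT_t2 acceleration (AUC 0.943, accuracy 0.854)
scalar-only (non-WBB) AUC: 0.865
```

Every balance-board model improves on the scalar-only AUC (0.89–0.94 vs
0.865 on this cohort) while the pooled threshold keeps specificity at or
above the 0.75 floor — the qualitative finding the pipeline is built
around. `analysis/05_report.py` writes the characteristics table and the
regression-curve figure; `analysis/06_recovery_experiment.py` checks
localization against the generator truth:

```
$ python analysis/06_recovery_experiment.py
...
Jaccard > 0.3 in 10/10 seeds (median 0.59); true window (2.0, 6.5) s
```

i.e. the significant region of the fitted curve recovers the time window
where the generator placed the class difference.

There is also a `gsdpred` console entry point (`simulate`, `ingest`,
`features`, `fit`, `crossval`, `report`) wrapping the same library calls
for ad-hoc use on any data laid out in the documented formats.

## Limitations

The synthetic generator reproduces the statistical structure the analysis
assumes, not balance-board physics; absolute performance numbers on
synthetic cohorts say nothing about performance on real patients. See
`docs/methods.md` for the generative model, parameter choices, numerical
details and known caveats (including the single-imputation-before-CV
leakage caveat and the behavior of the curve's pointwise bands under
quasi-separation).
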