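# Methods

This note records the models, parameter choices and numerical details
behind `gsdpred`, and what the synthetic experiments do and do not
demonstrate.

## Synthetic cohort generator

### Sway traces

Each 30 s balance test is a discrete-time mean-reverting Gaussian walk per
axis at the board's 0.02 s sampling interval:

```
x_i = (1 − κ) x_{i−1} + e_i,   e_i ~ N(0, s_i²),   x_0 = 0
```

`s_i = baseline_sd · subject_scale · pose_scale · effect_i`, clipped to
±`board_halfwidth` after filtering. The process is stationary, bounded in
practice, and its instantaneous velocity scale — the quantity the
functional covariates measure — is directly controllable, which is why it
was chosen over biomechanically detailed sway models. Defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `sampling_interval` | 0.02 | s | board-native rate |
| `duration` | 30 | s | test length |
| `baseline_sd` | 0.1 | board units/step | gives sway paths of a few board units |
| `mean_reversion` κ | 0.02 | — | weak pull to center; ~1 s relaxation |
| `board_halfwidth` | 20 | board units | the board's coordinate units/range are not standardized; this bound is arbitrary and rarely binds |
| `pose_scale` | 1.0/1.2/1.3/1.5 | — | harder poses (eyes closed, feet together) sway more |
| `class_velocity_ratio` | 2.0 | — | moderate class effect on step scale |
| `effect_window` | [2.0, 6.5] | s | where the class difference applies; early-window localization gives recovery tests a known truth |
| `subject_scale_sigma` | 0.4 | log units | between-subject sway heterogeneity (below) |
| `effect_sigma` | 0.35 | log units | between-subject effect heterogeneity (below) |

Device users (GSD+) receive the `class_velocity_ratio` multiplier on step
scale only inside `effect_window`, so their squared sway velocity is
elevated by the ratio squared there.

**Subject heterogeneity matters.** Two log-normal random effects are drawn
once per subject: a baseline sway multiplier (`subject_scale_sigma`) and a
within-window effect multiplier around its class mean (`effect_sigma`).
Without them the generator is degenerate as a testbed: averaging hundreds
of in-window samples across 4–8 tests makes any ratio above 1 almost
perfectly separable, logistic fits then diverge (infinite MLE), and no
confidence statement survives. With them, classes overlap the way real
cohorts do. A side effect worth knowing: with heterogeneous baselines the
*population-optimal* coefficient curve is not null outside the effect
window (out-of-window sway estimates the subject's nuisance scale and
enters with negative weight), so recovery experiments that compare against
a curve that is "truth-null outside the window" set `subject_scale_sigma=0`
(see `gsdpred.experiments`).

### Roster

Ages and grips are Gaussian with class-shifted locations (ages 79 vs 87,
right-grip 24 vs 16 kg, matching the magnitudes of the study population);
ordinal survey items are thresholded Gaussian latents with fixed cutpoints
(−1.5, −0.5, 0.5, 1.5) and class-specific means; yes/no items are Bernoulli
at class-specific rates; fall counts are shifted Poisson conditional on
having fallen. All survey items share a per-subject frailty factor through
a Gaussian copula (loading 0.6): marginal rates keep their configured
values, but items are positively correlated within subject, as
functional-status questionnaire items are in practice — independent items
would overstate the joint information and, again, produce separable
cohorts. Exclusion flags (equipment error / missing survey / missing
board data) are assigned to disjoint random subjects at the configured
counts; the default counts (21/39/2 of 268) reproduce the participant flow
the pipeline's filters must handle. Unable-to-complete subjects are drawn
only from GSD+ by default (configurable): someone unable to stand
unassisted for 30 s is overwhelmingly likely to be a device user.
Missingness is MCAR at `missing_rate` per cell among retained subjects,
capped at 4 cells per subject so those subjects stay imputable; flagged
survey-heavy subjects receive 6 empty cells.

### What the generator does not emulate

Realistic sway spectra (the AR(1) walk has a flat step spectrum),
pose-specific dynamics beyond a scale multiplier, learning/fatigue across
trials, time-of-day effects, board calibration error, and the full
dependence structure of real questionnaires. Passing tests on these
cohorts therefore demonstrates that the *pipeline* behaves as specified
under its own assumptions — not that the prediction task is solvable at
any particular accuracy on real patients.

## Ingestion

Feature order is fixed: age, sex (female = 1), 19 survey items, grips
R1/L1/R2/L2 — 25 features. Likert items encode 0–4 (health: Poor→0 …
Excellent→4; difficulty: No Difficulty→0 … Unable to do→4), yes/no items
0/1, counts as non-negative integers. Unknown vocabulary raises an error
naming the item.

Exclusion precedence for reporting is equipment error > missing survey >
missing board data (a subject counted once). The missingness gate sends
rows with 1–4 missing cells to imputation and drops rows with more.

Imputation is single (one completed dataset) predictive mean matching
within chained equations: per incomplete column, an OLS regression on all
other columns over complete cases; each missing cell copies the observed
value of one of the 5 donors with nearest fitted means, chosen uniformly;
10 sweeps; initialized at column medians. Imputed values therefore always
lie in the observed support of their column. Imputation runs once on the
full cohort before cross-validation — a small information leak across CV
folds, accepted deliberately because the imputed cells are ≤ 4 of 25
features for a handful of subjects; a fully nested imputation would be the
conservative alternative.

## Functional covariates

Velocity is the per-axis first difference divided by the local time step,
assigned to the right endpoint; acceleration is the same operation applied
to velocity. Resampling to the 0.1 s grid (300 points, 0.1 … 30.0 s) takes
the nearest sample in time, ties to the earlier sample; traces more than
0.2 s short are rejected by name. The covariate value is the pointwise
squared magnitude vₓ² + v_y² (summing the two axes, not over time — a
time-sum would collapse the curve to a scalar). Aggregates (trial 1, both
trials) are pointwise means, keeping them on the same scale as single
tests. 8 single tests + 2 aggregates × 2 kinds = 20 covariates.

## Functional logistic model

- **Basis:** 10 cubic B-splines, clamped, equally spaced interior knots on
  [0, 30] s; configurable. Ten functions give curves smooth at the few-
  second scale with modest degrees of freedom against n ≈ 200.
- **Quadrature:** the design entry ∫x(t)Bₖ(t)dt uses the trapezoid rule.
  Because the grid starts at 0.1 s, x is first linearly extrapolated to
  t = 0 from its first two grid values; this makes the rule exact for
  integrands linear in t on the full [0, 30] domain (x ≡ 1 integrates to
  exactly 30, x = t to exactly 450). Edge-spline entries still carry the
  O(h²) Euler–Maclaurin boundary term for general smooth x.
- **Fitting:** IRLS (Newton with step-halving, so the penalized
  log-likelihood is monotone non-decreasing), linear predictor clamped at
  ±35, weights floored at 1e-10. A light ridge (1e-4) applies to the basis
  coefficients only; scalar coefficients are never penalized. Convergence:
  relative penalized log-likelihood change ≤ 1e-8 (scale-guarded by
  max(1, |ll|)), or a plateau flatter than 1e-6 under detected separation
  (coefficient magnitude > 30) — near-separated fits stall just above a
  purely relative criterion while carrying no further information. The
  separation flag is always reported; covariance comes from the inverse
  penalized observed information. AIC uses the raw parameter count and the
  unpenalized log-likelihood (an effective-df version would subtract the
  ridge shrinkage, immaterial at 1e-4).
- **Selection:** backward AIC over the scalar features, ties to the
  earlier candidate; a non-convergent candidate removal is skipped with a
  warning. On null features this keeps each with probability
  P(χ²₁ > 2) ≈ 0.157 — about 4 of 25, the theoretical behavior of AIC
  stepwise, not an error.
- **Curves and bands:** β̂(t) = Σ bₖBₖ(t) with pointwise variance
  B(t)ᵀΣ_b B(t) and 95% bands (simultaneous bands would be wider; pointwise
  is the minimal reading of a "95% band"). The significant region is the
  set of maximal grid intervals where the band excludes zero. Two caveats
  follow directly: at the 5%-per-point error rate, a 15 s null stretch
  shows some spurious significant interval in roughly a quarter of
  replicates; and under quasi-separation the bands inflate and the region
  can be empty even when the curve's shape is right.
- **Prediction:** inverse logit of the linear predictor. A subject flagged
  unable to complete the tests is predicted GSD+ with probability 1.0
  outright — less stable than anyone who finished the tests — bypassing
  the model.
- Models carry at most one functional covariate; cohorts of this size
  cannot identify several regression curves at once.

## Evaluation

10-fold CV over a uniform random partition (fold sizes differ by at most
one; no stratification). Within each fold: backward selection on the
training scalars, then the functional fit on training subjects able to
complete the tests; unable subjects sit in folds and are scored through
the override but never enter fitting. Scalar selections are shared across
the 21 models (selection does not see the functional covariate). The
classification threshold is chosen once on the pooled out-of-fold
probabilities: the smallest candidate in {0} ∪ {observed probabilities}
with specificity ≥ 0.75 under "predict GSD+ iff p > threshold" — since
specificity is monotone in the threshold, this maximizes sensitivity
subject to the floor. One pooled threshold (rather than per-fold) is the
reading consistent with a single reported specificity per model. When many
probabilities saturate (quasi-separated training fits push test
probabilities to the clamp values), the achieved specificity can overshoot
the floor; the floor itself is always respected. AUC is the rank estimator
with ties counted ½ (scikit-learn's `roc_auc_score`; the test suite checks
it against brute-force pair counting).

The characteristics table reports median (IQR) + Kruskal-Wallis for
continuous variables (age, grips, fall counts) and N (%) + Fisher's exact
test for categorical ones; r×2 tables with r > 2 use a seeded Monte-Carlo
estimate (10⁵ draws) that samples the group-1 category counts from the
multivariate hypergeometric — the exact conditional null given the
margins, equivalent to label permutation — and applies the
probability-ordering criterion with the +1 correction.

## Problem sizes used by the tests and acceptance script

The acceptance script simulates the full 268-subject design (8 traces per
testable subject) and runs one cross-validated functional model; it
completes in well under a minute. Test simulations use cohorts of 200–400
subjects and 10–20 seeded replicates per Monte-Carlo claim; recovery
experiments use n = 400 with 4 traces per subject. These sizes put the
Monte-Carlo assertions comfortably away from their thresholds while
keeping the full suite fast.

## Known limitations

- Absolute synthetic performance (AUC ≈ 0.9 at default settings) is a
  property of the generator's chosen effect sizes, not evidence about real
  cohorts.
- Single imputation before CV leaks a small amount of information across
  folds (documented above).
- Pointwise bands do not control family-wise error over the 30 s domain.
- The board's coordinate units are not standardized; `board_halfwidth`
  and `baseline_sd` are in arbitrary board units.
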