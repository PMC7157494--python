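# Methods

This note documents the generative model behind the synthetic trial, the
estimator, the imputation procedure, the numerical choices, and the known
limitations. It is the design record for maintainers; empirical claims
here are limited to what the test suite and `scripts/acceptance.py`
themselves compute.

## Trial design emulated

- 1565 participants, 26 randomized weeks, plus a fully observed baseline
  week (week 0) recorded before randomization begins.
- Weekly randomization to {activity, sleep, mood, none}. Arm
  probabilities are uniform (¼ each) by default and configurable; the
  design gives no reason to assume imbalance. Two assignment modes:
  `independent` (i.i.d. weekly draws — the default analysis assumption)
  and `block` (the four arms permuted within consecutive 4-week blocks,
  modeling a without-replacement randomization as a sensitivity mode).
- Within an active week, each day delivers a notification independently
  with probability 0.5 → Binomial(7, 0.5) deliveries, mean 3.5.
- Message content alternates between two framing types (tips and life
  insights) per participant and category; within a (category, type)
  bucket, messages are drawn without replacement and the bucket is
  reshuffled when empty. The default bucket size is 7 per (category,
  type): at ~3.5 messages per active week and a ¼ category share this
  yields repeat intervals on the order of 16 weeks, which matches the
  intended no-repeat experience; exact real bucket sizes are unknown.

## Outcome-generating model

All generation happens on each measure's *analysis scale* — raw 1–10 for
mood, square-root for steps and sleep minutes — and is mapped back to
natural units afterwards. For participant i, week t:

    mu_it = c + gamma * B_i + rho * M_it
            + sum_k (b0k + b1k * M_it) * I(Z_it = k)
            + u_i + eps_it

    daily values: d_itj = mu_it + nu_itj,   j = 1..7

with u_i ~ N(0, subject_sd²), eps_it ~ N(0, resid_sd²), nu_itj ~
N(0, daily_sd²). The moderator M_it is the **realized** previous-week
average of the analysis-scale daily values, so the simulator is the exact
generative mirror of the analysis model: moderation flows through what
was actually observed, including daily noise. The baseline week is drawn
from the stationary distribution of the untreated lag-1 process
(stationary mean (c + u_i)/(1 − rho); stationary within-person variance
(resid_sd² + rho²·daily_sd²/7)/(1 − rho²)), and its average supplies both
the week-1 moderator and the baseline control B_i.

Scale handling: mood daily values are rounded to integers and clipped to
1–10 (the EMA instrument is a bounded integer scale; exact bounds are not
documented, so 1–10 was fixed as the natural reading of the reported
values). Steps and sleep are generated on the square-root scale,
truncated at 0, and squared back to natural units, which guarantees
nonnegative counts/minutes. Clipping happens after daily noise, before
weekly averaging.

### Calibration

Defaults were calibrated once so that complete-data weekly-average
marginals at n = 1565 match the observed trial summaries — mood mean 7.21
(SD 1.43), steps mean 8274 (SD 3285), sleep mean 6.54 h (SD 1.25 h) — and
the moderation coefficients equal the reported estimates (mood slopes
≈ −0.05 per category with per-category lines through the reported
endpoints; steps b1 = −0.039 on the sqrt scale, activity dimension;
sleep b1 = −0.075 on the sqrt-minutes scale, sleep dimension). The lag-1
coefficient rho = 0.5 splits weekly-average variance between a persistent
between-person component and week-to-week innovation in roughly the
proportions needed to hit the observed SDs; it is a calibration choice,
not an estimate from data. The variance budget per measure
(subject_sd, resid_sd, daily_sd) was solved from the stationary-variance
formulas above and then adjusted once against large simulations to absorb
the (small) effects of rounding and clipping.

### Missingness

Daily missingness is logistic in the week index and the previous week's
*observed* average (carried forward over fully missing weeks):
MAR by construction, never depending on the current unobserved value.
Defaults give self-reported mood more missingness (≈25% at week 1 rising
toward ≈50% by week 26) than the wearable streams (≈13% rising toward
≈25%), reproducing the qualitative attrition shape of a long mobile
study; the exact weekly percentages of the real trial are not published
as numbers and are not targeted. The baseline week stays fully observed
(the generator's convention; the imputer has a cohort-mean fallback for
externally supplied data without baselines).

## Aggregation

Weekly outcome = mean over available days of the transformed daily value
(**transform, then average**: an "average daily square-root step count"
is the mean of daily square roots, not the square root of the mean —
a regression test pins 5 vs √29 ≈ 5.385 on the worked series 4, 9, 16,
25, 36, 49, 64). Week t's moderator is week t−1's average; week 1 uses
the baseline week. Controls default to the baseline average of the
outcome plus the previous week's averages of the *other* two measures
(the outcome's own lag is the moderator and would be exactly collinear
if also included as a control); the set is configurable. Control
variables are used as-is (no standardization) — centering them would
only relabel the intercept, and the moderation contrasts are invariant
to it.

## Estimation

The design matrix contains the intercept, controls, the moderator, and —
for each active category k — the centered indicator I(Z=k) − p_k and its
product with the moderator. A binary mode collapses the three active
arms into one indicator centered at their total probability. Weights are
1 when the centering probabilities are the true randomization
probabilities (the trial's case); a general weight hook remains for
probability-mismatch experiments.

The fit solves the weighted least-squares normal equations; covariance is
the participant-clustered sandwich B⁻¹MB⁻¹ with B = Σᵢ XᵢᵀWᵢXᵢ and
M = Σᵢ XᵢᵀWᵢrᵢrᵢᵀWᵢXᵢ. No small-sample meat correction is applied by
default (1565 clusters); a t reference with clusters − parameters df is
available but off by default, and Wald tests use the standard normal
with ±1.96·SE intervals. Rank deficiency raises an error naming the
collinear columns (pivoted QR); a single cluster raises an inference
error.

Because centering uses known probabilities, the treatment-interaction
coefficients of the centered fit coincide exactly with those of the
uncentered saturated interaction regression (the centering only
reparameterizes the intercept and moderator terms by +Σ p_k b_k); a
brute-force refit oracle in the tests pins this equivalence, and the
statsmodels clustered-OLS covariance serves as an independent check of
the sandwich.

## Multiple imputation

Missing daily values are imputed on the analysis scale from a normal
linear model with intercept, scaled week index, previous-week average,
baseline average, day-of-week dummies, current-week arm dummies, **and
arm × previous-average interactions**. The interactions matter: they keep
the imputation model congenial with the moderation analysis — without
them, values imputed in treated weeks carry no moderation signal and the
pooled b1 is attenuated toward zero. Imputation is proper (per stream:
sigma² drawn from the scaled inverse-chi-square posterior, coefficients
from their normal posterior) and proceeds week by week so imputed values
feed forward into the next week's lagged predictor, respecting the
longitudinal and sequentially randomized structure. Imputed values are
clipped to valid ranges (mood 1–10, sqrt scales at 0). M = 20 by default.

Pooling uses Rubin's rules: Q̄ the mean estimate, B the between-imputation
sample variance (denominator M−1), Ū the mean within variance,
T = Ū + (1 + 1/M)B, and ν = (M−1)(1 + Ū/((1+1/M)B))², with a
Barnard–Rubin small-sample option. B = 0 falls back to the normal
reference. Only scalar coefficients are pooled (estimate and variance
per coefficient), not whole covariance matrices.

## Reporting

Effect curves are δ_k(m) = b0_k + b1_k·g(m) on the analysis scale with
pointwise variance v00 + g²v11 + 2g·v01. Square-root-scale effects are
retransformed by anchoring the no-notification mean at √m:
natural effect(m) = (√m + δ(√m))² − m. This anchor is one of several
defensible choices; it is adopted because it is self-consistent (solving
(√m+δ)² − m = e for δ and retransforming returns e to 1e−9, a tested
invariant) and reproduces the reported natural-scale endpoint pairs to
their printed rounding. Standardized effect sizes divide the
natural-scale effect by the observed SD of the weekly-average outcome
(1.43 mood points, 3285 steps, 75 sleep minutes). Reporting rounds mood
effects to 2 decimals, steps/minutes to integers, slopes to 3 decimals.
The pooled reference line in the per-category display is the
randomization-probability-weighted average of the category coefficient
pairs, which places it inside the convex hull of the category lines
under uniform probabilities.

## Operating characteristics and problem sizes

The validation suite uses a continuous, unclipped variant of the mood
process (so the true coefficients are exactly defined) and runs, at
n = 300 participants × 26 weeks:

- 500 replicates under b1 = (−0.052, −0.075, −0.039): mean bias of each
  moderation coefficient below 0.005 and 95%-CI coverage within
  0.93–0.97;
- 500 replicates under b1 = 0: type-I error of the nominal-0.05 test
  within 0.03–0.07.

These sizes give Monte-Carlo standard errors of ≈0.001 on the bias and
≈0.01 on coverage, small enough to detect meaningful miscalibration
while keeping the suite to a couple of minutes. Misspecification
robustness (omitting a truly predictive baseline control leaves the
moderation coefficients unbiased) is checked at n = 500 over 30
replicates.

## Known limitations

- **Bounded mood scale.** On the integer 1–10 scale, ceiling effects
  make the true conditional mean slightly nonlinear near the top, so
  WCLS estimates of the latent slopes are mildly attenuated (≈10–20%
  depending on the coefficient). This is a property of any linear
  analysis of a bounded scale, not of the estimator; the validation
  suite therefore targets the continuous process, and study-size runs in
  the acceptance script report what a bounded-scale analysis actually
  yields.
- **Imputation under heavy attrition.** With mood missingness rising to
  ~50%, the pooled moderation estimate remains mildly attenuated
  relative to the complete-data fit even with a congenial imputation
  model (the imputer's daily-level linear model is not the exact
  generative process). The MCAR validity check bounds this at the
  2-SE level.
- The generator works at daily resolution: minute-level wearable
  streams, prompt-timing windows, and notification transport are out of
  scope. Missingness is MAR by construction; not-at-random sensitivity
  analyses are not implemented.
- Real data features not emulated: work schedules, weekday/weekend
  structure, self-selection of participants, and message-content
  effects. Passing tests demonstrate correctness of the pipeline under
  the stated generative model, not fidelity of that model to any
  particular cohort.
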