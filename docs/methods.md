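# Methods

## Model

All measurement is under the Rasch rating-scale model (RSM). A response
of person *n* to item *i* in categories 0..M has

    P(X_ni = k) ∝ exp( Σ_{j≤k} (θ_n − δ_i − τ_j) ),    empty sum = 0,

with person measure θ_n, item difficulty δ_i and step calibrations τ_j
shared by every item (this is what distinguishes the RSM from the
partial-credit family, which the package deliberately does not
implement). τ_j is the logit at which categories j−1 and j are equally
probable. Expected score is Σ k·P_k; item information equals the
category-score variance Σ k²P_k − (Σ kP_k)², which is also the Fisher
information for θ. Category probabilities are computed from partial-sum
exponents shifted by their maximum before exponentiation, so extreme
logits cannot overflow.

The instrument's survey-facing 1–4 Likert codes are stored on disk as
1–4 and represented internally as 0–3 (step indexing starts at j = 1);
every file header states its coding.

## Person estimation

`estimate_theta` solves the score equation by Newton–Raphson:
θ ← θ + (Σx_i − ΣE_i(θ)) / ΣW_i(θ), with per-iteration steps capped at
1 logit, θ clamped to [−10, 10], tolerance 0.001 logits and at most 50
iterations (the measurement context makes tighter tolerances
meaningless; the cap and clamp only guard early iterations from
overshoot). The standard error is 1/√(ΣW_i) at the solution. All-minimum
and all-maximum raw scores have no finite maximizer; they are pulled
0.25 score units toward the interior — a long-standing Rasch convention —
and flagged `extreme`. The estimator is verified against a brute-force
likelihood grid (step 0.001 over [−10, 10]) to within 0.005 logits.

## Joint calibration (JMLE)

`jmle_calibrate` alternates single Newton steps over person measures,
item difficulties and shared thresholds until the largest parameter
change falls below 1e-4 logits (default; at most 500 sweeps). The
threshold update uses the cumulative-category score equation: for each
step j, dL/dτ_j = Σ(P(X≥j) − 1{x≥j}) with curvature −Σ P(X≥j)(1−P(X≥j)).
Missing cells are simply omitted from every sum; persons or items whose
observed responses have no variance are dropped from parameter
estimation with a warning (every person with data still receives a final
measure).

**Identification.** The likelihood is invariant to two independent
location shifts (persons with items, and items with thresholds).
Unanchored runs are identified by mean δ = 0 and Σ τ = 0. When item
difficulties are anchored, one invariance remains — a joint shift of
persons and thresholds — so anchored runs additionally keep Σ τ at the
anchor scale's value: estimates are expressed in the anchor frame. This
choice is what makes anchored recovery experiments meaningful; any other
convention recovers the generating thresholds only up to a constant.

**Bias correction.** JMLE structural estimates are overdispersed because
person measures are estimated jointly from finitely many responses
(classical JMLE inconsistency). The package applies the first-order
test-length correction — shrinking the centered threshold structure (and
unanchored difficulties) by (L−1)/L for mean test length L — by default
(`CalibrationConfig.bias_correction`). At L = 24 the raw overdispersion
is 3–4% of the threshold spread, about 0.1 logit on the outer
thresholds; the correction reduces recovery error to ~0.05 logit.
Disable it when comparing against other pure-MLE software.

Misfit screening applies the conventional 0.5–1.5 band to infit MNSQ,
single-pass (no purify-and-refit), with closed interval boundaries.

## Fit statistics

Standardized residual z_ni = (x − E)/√W. Outfit is the unweighted mean
of z²; infit the information-weighted Σ(x−E)²/ΣW. Both have expectation
1 under the model (slightly less in-sample, since jointly estimated
measures absorb ≈1/L of the residual variance). Standardized Z uses the
Wilson–Hilferty cube-root transform with the Wright–Masters moment
variances (fourth central moments of the category distributions).

## Reliability, SEM, dimensionality, categories

Person-separation reliability = (observed variance of non-extreme
measures − mean squared SE)/observed variance, floored at 0. The CAT
stopping SEM is SD × √(1 − reliability) of a reference calibration;
with the packaged reference values (SD 1.99, reliability 0.88) it
truncates to 0.68.

Residual PCA eigen-decomposes the item-by-item correlation matrix of
standardized residuals. Variance explained by the measures is
100·var(E)/(var(E) + mean W) over observed cells. The first contrast is
the largest residual eigenvalue; its variance share is expressed against
the *total* variance — residual eigenvalues sum to n_items units, so the
total is n_items/(1 − explained fraction) units. Under this convention
an eigenvalue of ~1.8 on a 24-item scale is ~4% of variance; dividing by
item count alone would misstate the share and would flag even model-true
data (the null largest eigenvalue of a 24-item residual correlation at
n = 1000 is ≈1.35). The screen reported by the package (eigenvalue < 3,
share < 5%, explained-variance cutoff 60%) is evidence, not policy:
all three numbers are returned and the caller decides, since instruments
are routinely accepted on the contrast criteria with explained variance
short of 60%.

Category diagnostics evaluate the four Linacre guidelines: average
measures advance with category, step calibrations advance, adjacent
advances ≥ 1.4 and < 5.0 logits. Empty categories leave the affected
flag undetermined rather than guessed.

## Adaptive sessions

The starting measure is mapped from a 1–4 global self-rating; the
default map {1: −2.0, 2: −0.5, 3: 0.5, 4: 2.0} is deliberately coarse
(monotone, spanning the central range) and config-overridable — the
procedure only needs a rough entry point, since estimation takes over
after burn-in. Three burn-in responses are collected at the initial
measure (items still chosen by maximum information there, ties to the
lowest id); from the fourth response on, θ is re-estimated after every
answer. Stopping: SE ≤ SEM target once the 10-item minimum is reached,
or the bank/maximum length is exhausted. An optional running-outfit
abort (threshold 10, off by default) exists for kiosk deployments where
a wildly inconsistent record should end the session early; the separate
aberrance *flag* (outfit > 2.0, |z| > 1.96 per response) is always
computed at the final measure.

The session SE sequence is non-increasing up to re-estimation wiggle:
information is additive at a fixed measure, but each step's SE is
evaluated at the newly estimated measure, which can move; observed
violations are below 0.01 logits. The session log stores every response,
so the final measure is exactly reproducible offline from the log.

## Synthetic cohorts

`simulate_cohort` draws person measures from N(mean, sd) — defaults
300 persons, mean 2.30, sd 1.99, matching the reference calibration
cohort — or from any user-supplied quantile function, then draws
responses by inverse CDF over the model probabilities. All randomness
flows through one `numpy` generator seeded from the spec. A per-item
difficulty shift emulates localized year-on-year change for
group-comparison studies.

What the generator does *not* emulate: real response styles (central
tendency, acquiescence), locally dependent items, multidimensional
traits, missingness mechanisms, or demographic structure. Passing tests
on simulated data therefore demonstrates internal consistency of the
estimation machinery — parameter recovery, calibrated error rates, fit
statistics behaving as designed — not robustness to the violations real
surveys exhibit.

## Group comparisons

Item contrasts use Welch's unequal-variance t with Satterthwaite degrees
of freedom on raw category scores (a logit-scale mode exists but is off
by default: practitioners compare item scores). The Welch choice matters
in small unbalanced strata: a (6, 2)-sized contrast has df ≈ 2, turning
t = 3.0 into p ≈ 0.095 where a pooled test would claim p ≈ 0.02.
Demographic composition tables use Pearson chi-square with Yates
continuity correction if and only if the table is 2×2. No
multiple-testing correction is applied; reports state the number of
tests performed.

## Problem sizes used in verification

The package's own checks run at sizes chosen to make the statistics
stable on one CPU in a few minutes: threshold-recovery at 2000 simulated
persons, reliability and dimensionality at the survey-scale 300, PCA
replication over 20 seeds, person-fit calibration over 200–300 adaptive
sessions, and estimator-vs-grid agreement on 200 random patterns.

## Known limitations

- JMLE only; no conditional or marginal maximum likelihood, and the
  (L−1)/L correction is first-order, so residual bias of a few
  hundredths of a logit remains at L = 24.
- Rating-scale parameterization only (no partial credit, 2-PL or graded
  response); all items must share one threshold vector.
- No item-exposure control or content balancing in the CAT driver.
- Fit-statistic null distributions are approximate (Wilson–Hilferty);
  at large n the in-sample MNSQ expectation sits slightly below 1.
- The packaged bank's misfit rows carry no difficulty estimates and are
  excluded from every calibrated-item operation.
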