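# Methods

## The multicomponent model

Body composition of boys aged 8–18 is represented by three DXA components —
fat mass (FM), bone mineral content (BMC) and lean soft tissue (LST), all in
kg — predicted *simultaneously* from five anthropometric inputs: stature
(cm), body mass (kg), suprailiac skinfold (mm), horizontal abdominal skinfold
(mm) and maturity offset (PHV, years from peak height velocity). The model is

    Y = X B + E

with no intercept: at X = 0 all components are zero, and the prediction is
homogeneous of degree one in the measurements. Because the weight
coefficients nearly partition unity across the three responses
(0.3139 + 0.0392 + 0.6419 = 0.9950), predicted totals FM + BMC + LST track
measured body mass closely — a structural sanity check used in the tests.

The joint (multivariate) formulation estimates the same coefficients as three
univariate regressions (a property of least squares with a shared design,
verified to 1e-10 in the tests) but supports simultaneous hypothesis tests
across responses and a single cross-validation of the whole system.

`predict_components` refuses nothing inside the mathematical domain: inputs
outside the development sample's observed ranges yield predictions plus an
`ExtrapolationWarning`, and negative predicted masses (possible for an
intercept-free linear map on extreme inputs) are returned as-is with a
warning, never clipped. Units are fixed (cm, kg, mm, years); no unit
inference is attempted.

Weight is scale-measured body mass, the field measurement the model is meant
for, not a DXA-derived total.

### Maturity offset

When PHV is not measured it is computed with the Mirwald boys' equation from
age, stature, sitting height and body mass (leg length = stature − sitting
height). In the worked-example fixture PHV = −1.6 y is treated as a given
input because the example does not include age or sitting height.

## Fitting and diagnostics

* **Estimation.** Normal equations with the classical inverse,
  `B = (X'X)⁻¹X'Y`, after an explicit QR-based rank check that names the
  dependent columns on failure. A QR solution is used as an independent
  cross-check in the tests (agreement to 1e-8 relative).
* **R².** For intercept-free fits R² and adjusted R² use the *uncentered*
  total sum of squares `Σy²` with adjustment factor `n/(n−p)` — R's
  `summary.lm` convention for no-intercept models, which is the convention
  the published precision statistics follow. With an intercept the usual
  centered convention applies. `SEE_residual = sqrt(SSE/(n−p))`.
* **Pillai's trace.** Terms are tested by comparing the full model with the
  model omitting them: `H = E_reduced − E_full`, `V = tr(H(H+E)⁻¹)`, with the
  standard F approximation (s = min(responses, terms); exact for single-term
  tests, which is what the selection procedure uses). When `‖H‖ ≈ 0` (e.g.
  noise-free data with a null term) V = 0 is returned even though H + E is
  singular. Calibration is verified by simulation: the null rejection rate at
  α = 0.05 is 0.05 ± 0.02 over 1000 replicates.
* **Collinearity.** Ratio of the largest to smallest eigenvalue of the raw
  (unscaled, uncentered) `X'X`: weak < 100, moderate 100–1000 (boundaries
  inclusive), severe > 1000; a smallest eigenvalue at machine tolerance is
  reported as an infinite ratio, severe. The raw matrix is used because the
  magnitudes this classification refers to arise from unscaled anthropometric
  designs; a correlation-scaled 5-variable matrix could rarely reach the
  moderate band.
* **Selection.** Per-response forward–backward stepwise with partial-F entry
  and removal tests (defaults α = 0.05, configurable — the thresholds that
  produced the published five-variable model are not recorded anywhere, so
  the full elimination order is logged and replayable). The per-response
  retained sets are intersected; intersection members whose single-term
  Pillai p-value in the joint model exceeds the removal threshold are then
  pruned, provided removal keeps the collinearity category at most moderate.
  An empty intersection is a valid (logged) outcome, not an exception.

## Cross-validation

PRESS is the sum of squared leave-one-out prediction residuals. `press_loo`
uses the leverage identity `e(i) = e_i/(1−h_ii)` (one fit); `press_naive`
performs the literal n refits and exists purely as an oracle — the two agree
to 1e-8 relative across randomized problems. Leverages within 1e-8 of 1 are
an error naming the observation.

`R²_PRESS = 1 − PRESS/((n−1)·SD²)` always uses the centered total sum of
squares (this is the convention the published cross-validation block follows,
unlike its R² block; both conventions are therefore implemented exactly where
each applies). R²_PRESS ≤ R² holds for every fitted problem, since
PRESS ≥ SSE and the centered total SS is no larger than the uncentered one;
negative values are possible for poor models and are reported as-is.

`rmse_press = sqrt(PRESS/n)` is this package's per-observation summary of the
leave-one-out error. It is deliberately *not* called SEE_PRESS: the published
per-response "SEE_PRESS" values are numerically inconsistent with any
function of the published PRESS values and n that we could identify, so the
package reports its own well-defined quantity instead of claiming to
reproduce that statistic.

**Technical error of measurement.** The standard Dahlberg form over m
duplicate pairs, `TEM = sqrt(Σd²/2m)`, `TEM% = 100·TEM/mean` (the source
literature cites but does not print a formula; Dahlberg is the field
standard).

## Synthetic cohorts

No subject-level data is deposited with the published model, so all fitting
and validation experiments run on synthetic cohorts that emulate the
development sample (n = 408 boys, 8–18 y):

* **Targets.** Printed per-variable means, SDs and observed ranges, and the
  printed pairwise correlations among stature, weight, sitting height, age,
  PHV, the two skinfolds and the three components.
* **Completion.** Two groups of pairwise correlations are not printed and are
  imputed by documented rules: (1) the FM/BMC/LST pairwise correlations are
  taken from the covariance implied by the published model itself,
  `cov(Y) = B'ΣₓB + diag(SEE²)` — this choice is self-consistent (it
  reproduces the printed response SDs to ≤ 0.04 kg) and keeps the assembled
  10×10 matrix nearly positive semi-definite (min eigenvalue −0.003, so the
  nearest-correlation repair moves entries by < 0.005, preserving every
  printed value to its printed precision); (2) sitting height, which has no
  printed correlations at all, is anchored to stature at r = 0.95 (sitting
  height tracks stature closely during growth) and routed through stature for
  every other pair, r(Sh, v) = 0.95·r(Ht, v).
* **Marginals.** Gaussian copula with truncated-normal marginals. For each
  variable the underlying (μ, σ) is calibrated so the *truncated*
  distribution has exactly the target mean and the closest feasible SD —
  naive truncation would bias skewed variables (fat mass's lower bound sits
  at −1.07 SD) by ~20 %. Two printed SDs are infeasible for any truncated
  normal on their printed range and are matched as closely as possible: age
  (target 2.99 y on [8, 18], maximum ≈ 2.89, achieved 2.84 — the sample is
  nearly uniform in age, which no truncated normal can exceed) and suprailiac
  skinfold (10.2 → 10.12 mm).
* **Dependence.** The copula correlation is adjusted per pair (inverse-NORTA
  via Gauss–Hermite quadrature) so the *induced Pearson* correlations hit the
  targets despite the nonlinear marginal transforms, then repaired to the
  nearest PSD matrix. At n = 5000 the sample correlations deviate from the
  targets by ≤ ~0.03 (sampling noise), and sample means sit within 2 % of
  targets (for PHV, whose mean of −0.5 y is only 0.2 SD, the equivalent
  band is 0.05 SD).
* **Options.** Skinfolds can alternatively use range-truncated lognormal
  marginals (right-skewed, moments then approximate); PHV can be recomputed
  from the Mirwald equation instead of drawn jointly, for consistency
  testing. Both are off by default: the printed correlation table treats PHV
  as a measured covariate, and Gaussian-with-truncation is the simplest
  distributional reading of the printed moments (the source states no
  distributional form — this is a modeling choice).
* **Model-driven cohorts** draw only the five predictors and construct
  responses as `XB + ε` with configurable per-response noise SDs (defaults:
  the published residual SEEs 1.666, 0.1923, 1.748 kg), enabling
  parameter-recovery experiments with known truth.
* **Duplicates** for TEM studies add Gaussian error with SD = TEM·√2 to each
  first measurement, making the Dahlberg estimator consistent for the target.

All generators are pure functions of (arguments, seed).

### What passing tests do and do not show

The generator reproduces first and second moments and ranges, not real
growth-curve dynamics: no age-group heteroscedasticity, no athlete/
non-athlete or ethnicity structure, no measurement rounding, and Gaussian
(or optionally lognormal) shapes rather than the true skinfold
distributions. Parameter-recovery and R²/R²_PRESS-band results on these
cohorts therefore demonstrate that the *fitting and validation machinery* is
correct and that the published precision statistics are mutually consistent
at the published sample size — they do not re-validate the published
coefficients against new subjects.

## Problem sizes and numerical choices

* Recovery experiments: 200 replicates of n = 408 (the development-sample
  size) with the published coefficients and residual SDs; bias is judged
  against 3 Monte-Carlo SEs per coefficient (a 1-SE band would fail ~2/3 of
  the time per coefficient for a perfectly unbiased estimator).
* PRESS oracle equivalence: 50 randomized problems with n ≤ 60, p ≤ 6.
* Pillai calibration: 1000 null replicates at n = 30, q = 3 responses.
* Rank checks use QR diagonals at 1e-10 relative tolerance; leverage
  tolerance for PRESS is 1e-8; the nearest-PSD repair targets minimum
  eigenvalue 1e-7.
* Cohort text I/O writes `%.17g` and reads with round-trip float parsing, so
  file round trips are bit-exact.

## Known limitations

* The published model is for boys 8–18 only; no female or adult equations,
  and no alternative skinfold equations are provided.
* The selection procedure cannot be validated against the original
  development run (the eliminated variables and their order were never
  reported); it is validated on synthetic designs with known structure.
* One printed worked-example cell (stature × BMC coefficient) is internally
  inconsistent with its own factors and column total; the package reproduces
  the arithmetically consistent value.
* Whether the published eigenvalue ratio was computed on raw, centered or
  scaled predictors is unrecorded; this package documents and uses raw X'X.
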