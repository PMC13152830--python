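# Methods

## Model

The package implements the bivariate *dual* latent change score model for
`T` waves of two constructs, here family functioning (FF, `x`) and
externalizing problems (EP, `y`).  Observed composites load with fixed unit
loadings on latent true scores; successive true scores satisfy
`x_t = x_{t−1} + Δx_t` with the latent change

```
Δx_t = s_x + β_x x_{t−1} + γ_xy y_{t−1} + ξ_xy Δy_{t−1} + φ_x Δx_{t−1}
```

(the `ξ` and `φ` terms exist from the second change onward, i.e. t ≥ 3),
and symmetrically for `y`.  Structural choices, each of which was genuinely
open:

* **Wave-1 change.** There is no change variable at wave 1; the first
  change spans waves 1→2.
* **Intercept factors.** `i_x`, `i_y` are the wave-1 true scores
  themselves, not separate factors loading on every wave.  Their means and
  variances are free.
* **Change-score residuals.** Latent changes carry no unique residual
  beyond the dynamic terms; all stochastic input enters through the
  intercepts, the slopes, and measurement error.  This is the standard dual
  change score convention; the alternative (per-change disturbances) adds
  `T−1` variance parameters and erodes identification at `T = 4`.
* **Intercept/slope covariance block.** All six covariances among
  `(i_x, s_x, i_y, s_y)` are free by default (toggleable); the data should
  decide how the baselines and slopes of the two constructs are coupled.
* **Equality over time.** With the default options each of
  `β, φ, γ, ξ, σ²` carries exactly one label across waves, giving the
  14 structural labels plus 10 block (co)variances = 24 free parameters
  against 44 sample moments (df = 20) at `T = 4`.
* **Covariates.** Exogenous observed covariates (gender, age) regress onto
  the four intercept/slope factors only, not onto individual change
  scores — the conventional reading of "controlling for individual
  differences".  Moments-only analyses cannot include them (published
  correlation tables carry no covariate moments); reports say so
  explicitly.

## Estimation

**ML on summary moments.** The discrepancy is the normal-theory function
`F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (m̄−μ)'Σ⁻¹(m̄−μ)`; the supplied
covariance matrix is used exactly as given (whether it carries the `n` or
`n−1` divisor is the caller's convention), and `χ² = (n−1)·F` — the Wishart
convention, chosen so results are comparable with mainstream SEM software.

**FIML on raw data.** The casewise log-likelihood is accumulated over
missingness patterns using pattern-marginal implied moments (sufficient
statistics per pattern, so complete data cost the same as a moments fit).
`χ²` is the likelihood ratio against the saturated multivariate normal,
fitted by EM under arbitrary missingness.  No value is ever imputed.

**Baseline and indices.** The baseline for CFI/TLI is the independence
model with free variances and means, closed form in both estimation modes
(for moments ML its discrepancy is `−ln|R|`).  RMSEA uses
`sqrt(max(0, (χ²−df)/(df(n−1))))` with a 90% interval by noncentral-χ²
inversion (lower bound clamped at 0); SRMR is the covariance-residual
version, means excluded.  `df = 0` yields not-applicable markers, never
division errors.

**Standard errors** come from a central-difference Hessian of −2 log L
built on the analytic gradient.  A non-positive-definite or unevaluable
information matrix yields missing SEs with a warning — never fabricated
numbers.  Both unstandardized and standardized solutions are always
reported side by side, because the reporting scale of published
coefficients in this literature is often ambiguous; standardized values
rescale each path by the implied SDs of its endpoints (a label equated
across waves reports its first cell; all per-cell values are retained).

## Optimization and the convergence criterion

The primary optimizer is **Fisher scoring with Levenberg–Marquardt
damping**: the expected information
`H_ab = tr(W ∂Σ_a W ∂Σ_b) + 2 ∂μ_a' W ∂μ_b` is exact and positive
semidefinite, which matters because this model family produces extremely
anisotropic likelihoods.  A log-variance L-BFGS pass serves as escape
hatch, with seeded multi-start (default 5 jittered starts) on failure.
Gradients of both objectives are analytic (RAM-derivative chain rule).

Convergence has two tiers:

1. gradient inf-norm below `1e−8 × max(1, |objective|)` (scale-relative,
   since the FIML objective is of order `n`), or
2. *function-improvement exhaustion*: no damped scoring step of any length
   reduces the objective by even one floating-point ulp, i.e. the
   likelihood is flat to machine precision around the iterate.

Tier 2 exists for a documented scientific reason.  The dual change score
model with both `φ` and `ξ` free is **empirically underidentified on some
datasets** even though it is locally identified at generic parameter
values (verified by the rank of the moment Jacobian): the mean equations
are nearly collinear whenever the wave means barely move, and the
likelihood then descends a curved, asymptotically flat valley along which
`φ`, `ξ` and the slope means grow without bound while the implied moments
barely change.  On such data the practical MLE is wherever float64 runs
out; a fit that ends there is reported `converged=True` with an explicit
ridge warning ("estimates on the ridge are not separately interpretable")
and, typically, unavailable standard errors.  The published-moments
fixture in this package is exactly such a dataset — which is consistent
with the implausibly large slope-mean coefficients the original analysis
reports against an observed total mean change well below 1 score point.
Interpret the *fit* of that model, not its individual ridge coordinates.

Negative variance estimates are possible (scoring runs in the raw
parameter space) and produce an explicit inadmissible-solution warning.

## Measurement invariance

Longitudinal invariance is tested in a single-group model with one factor
per wave — the estimable form of "multi-group CFA across time points" for
repeated measures on one sample.  Identification is by marker item: first
loading fixed at 1 and first intercept at 0 at every wave, factor means
free at every wave (fixing the wave-1 factor mean instead would force the
marker item's mean to zero — impossible for 3-point items centred near 2).
Same-item residuals covary freely across all wave pairs (toggleable).
Metric equates non-marker loadings across waves; scalar additionally
equates non-marker intercepts.  Items are treated as continuous under
normal-theory ML — a documented limitation shared with the analysis the
package replicates; no ordinal estimator is provided.

The ladder is fitted most-restricted-first with warm starts in both
directions (equated solutions expanded wave-wise, free solutions contracted
by averaging), keeping the better fit per level.  This keeps the
discrepancies monotone (`F_configural ≤ F_metric ≤ F_scalar`) even on
degenerate inputs.  A warm start that lands exactly on the singular
boundary is blended toward the data-driven start until the implied
covariance is positive definite.

Decision rule: a step is rejected when the CFI *decrease* exceeds the
threshold (default 0.01); ΔCFI is stored signed (later minus earlier).
Literally duplicated item columns make the empirical covariance singular
and the likelihood unbounded; in that case a ridge of `1e−6 × mean
variance` is added consistently to all data second moments (objective,
saturated reference, baseline) with a warning, which keeps every χ² and
ΔCFI well defined.

## Synthetic data

The generator module emulates the statistical structure of a four-wave
study of 598 enrolled adolescents (468 completers) with a 5-item 3-point
family-functioning index and a 10-item 3-point externalizing scale:

* **Moment-calibrated composites.** Multivariate normal draws from the
  embedded published moment structure (8 variables; FF means ≈ 11.1–11.6,
  SDs ≈ 2.2–2.3; EP means ≈ 15.5–16.1, SDs ≈ 3.0–3.1; cross-construct
  correlations −0.15…−0.38).  `exact` mode applies the affine correction
  that makes the sample moments match to machine precision regardless of
  seed.  Composites are continuous; mild range overflow is accepted rather
  than truncating, because truncation would distort the calibrated
  correlations (a clipped variant exists but is off by default).
* **Generative trajectories.** `simulate_lcs` draws `(i_x, s_x, i_y, s_y)`
  from a 4×4 normal block and iterates the coupled recursion, adding
  measurement error.  The fixed recovery condition
  (`recovery_parameters()`) uses intercept means/variances on the study's
  score scales, FF drifting down and EP up by a few tenths of a point per
  wave, couplings with the published sign pattern (γ > 0, ξ < 0) at
  published magnitudes, autoregressions of 0.30, and error variances below
  the intercept variances — strong enough dynamics that the model is well
  identified at n = 468 (the recovery study is meaningless on a ridge).
* **3-point items.** Items within a wave share one construct factor
  (exchangeable loadings); wave factors correlate with geometric lag decay
  (0.45 per lag).  Two thresholds per wave are derived by moment matching
  (item mean and variance from the target totals).  When a Cronbach's α
  target is given, the latent inter-item correlation is calibrated by
  root-finding through bivariate-normal rectangle probabilities so the
  *discretized* items hit the target — raw latent correlations understate
  α by ≈ 0.06–0.08 after 3-point discretization.  Pooled α targets: 0.78
  for the 5-item construct (published per-wave 0.75–0.80), 0.66 for the
  10-item construct (published 0.63–0.68).  Infeasible targets raise
  errors carrying the feasible bound.
* **Missingness.** MCAR blanks cells independently.  MAR dropout censors
  all waves after a dropout wave whose per-wave hazard is logistic in the
  standardized wave-1 score (slope 0.6 by default — moderate selectivity);
  the intercept is found by root-finding so the expected completer share
  hits the target (e.g. 468/598 = 78.3%).  Root-finding the *intercept*
  rather than the slope is deliberate: the level parameter reaches any
  target rate monotonically for any fixed selectivity.  The enrolment
  counts reported per wave in the source are non-monotone (participants
  returned after missing a wave); the generator targets only the
  598 → 468 completer contract.

What the generator does **not** emulate: non-normal composite margins,
item-level local dependence beyond the shared factor, returning dropouts,
MNAR mechanisms, or any covariate–outcome dependence (simulated gender and
age are null covariates).  Passing recovery and invariance tests on these
data therefore certify the *estimator and decision machinery*, not the
robustness of the original findings to violations of normality or MAR.

## Numerical choices

* Convergence tolerances: gradient `1e−8` (scale-relative), LM damping
  `λ ∈ [1e−10, 1e+50]` stepping ×10 down/÷3 up, iteration cap 5000.
* Correlation fixtures with smallest eigenvalue in `(−1e−8, 0)` are
  repaired by eigenvalue clipping at `1e−10` with diagonal renormalization;
  anything more indefinite is an error.
* Covariance symmetry is required to `1e−10`; the missing marker is NaN at
  the reader layer (a declared sentinel is mapped there and nowhere else).
* Singular empirical covariances trigger the documented `1e−6`-scale ridge;
  the EM-saturated log-determinant additionally carries a `1e−10` relative
  eigenvalue floor as a last-resort guard.
* Rows with no observed modeled variable are dropped with a warning;
  a variable that is entirely missing is an error.
* Ties in the ΔCFI rule: a decrease exactly equal to the threshold is
  accepted (the rule rejects only when the decrease *exceeds* it).

## Problem sizes used by the test suite

The suite exercises the pipeline at sizes chosen to make the statistical
assertions sharp but cheap: 200 replicates at n = 468 for recovery, bias,
coverage and SE calibration; n = 100,000 for large-sample moment and
coupling convergence; n = 200,000 for the correlation-endpoint
reproduction; 10 replicates at n = 1,000 per decision-rule scenario of the
invariance ladder; n = 5,000 with 20% MCAR for the FIML recovery check.

## Known limitations

* No Bayesian estimation, robust/bootstrap standard errors, or
  limited-information categorical estimators; items are continuous-ML.
* No partial-invariance search, strict (residual) invariance level, or
  alignment method.
* The single-group invariance model assumes the same participants at every
  wave; it is not a literal multiple-group analysis.
* On empirically underidentified data the reported point estimates are
  ridge coordinates; only the fit statistics and the warnings are
  interpretable there.
* Time-varying covariates, nonlinear or regime-switching change models,
  and multiple-indicator constructs inside the change layer are out of
  scope.
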