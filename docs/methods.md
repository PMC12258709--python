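# Methods

## Model and assumptions

The package treats the timescale of a weakly stationary, strong-mixing
process as a *projection* parameter: the decay rate of the best
exponential approximation of its autocorrelation, not a parameter of an
assumed data-generating model. Two projections are implemented.

**Time-domain linear projection (LLS).** `phi*` minimizes
`E[(X_t - phi X_{t-1})²]`, giving `phi* = E[X_{t-1}²]⁻¹ E[X_t X_{t-1}]` —
the lag-1 autocorrelation. Its sample version is the closed-form
no-intercept regression slope. No AR(1) assumption is made: if the process
is not AR(1), the projection errors are heteroskedastic and autocorrelated,
which the standard errors (below) accommodate.

**Autocorrelation-domain nonlinear projection (NLS).** `phi*` minimizes
`E[(rho_k - phi^k)²]` over lags `k = 0..K`; the sample version minimizes
`S(phi) = (1/K) Σ_k (rho_k - phi^k)²` on the sample ACF. The lag-0
residual is identically zero and its derivative is defined as zero; both
stay in the sums. Because it pools many lags, this projection targets a
*different* population parameter than the time-domain one whenever decay
is not exactly exponential, and the two estimators are reported as
distinct methods rather than interchangeable ones.

Both map to a timescale by `tau = -1/log|phi|`, the real-valued lag at
which `|phi|^tau = 1/e`. Conventions at the boundary: `tau = 0` at
`phi = 0` (limit), `tau = +inf` with a `nondecaying` flag at `|phi| >= 1`,
and negative `phi` uses `|phi|` throughout. These are total-function
conventions so that mass-univariate runs never abort on a bad vertex.

## Estimation details

* **Sample ACF.** The lag-scaled estimator divides each lag-`k` cross-sum
  (`T-k` terms) by the full-sample sum of squares, shrinking high lags
  toward zero and keeping `|rho_k| <= 1`. Computed via FFT; a brute-force
  double-sum oracle in the test suite confirms equality to round-off.
* **NLS optimizer.** Levenberg-Marquardt (MINPACK through
  `scipy.optimize.least_squares`, analytic Jacobian), stopping when the
  step size drops below the configured tolerance (default `1e-6`,
  maximum 1000 evaluations; non-convergence returns the last iterate with
  `converged = False` and a warning). `S(phi)` is a degree-`2K` polynomial
  and can be multimodal on noisy curves, so the iteration starts from the
  best of the lag-1 autocorrelation (clipped to ±0.999) and a closed-form
  scan of a fixed 1e-3 grid over (-0.999, 0.999) — the cross term
  `Σ rho_k phi^k` by Horner evaluation, the power sum by a geometric
  formula. Since the polish step only decreases the objective, the
  returned estimate dominates the whole grid by construction. Estimates
  escaping the open unit interval are clipped back to ±(1 - 1e-8) and
  flagged `nonstationary_estimate`.
* **Default lag count.** `K = T - 1` (all available lags) when fitting the
  NLS to data, matching the simulation design; configurable. The
  estimator's sampling variance is nearly flat in `K` beyond a few dozen
  lags, so this choice trades nothing measurable for simplicity.
* **Centering.** Inputs are demeaned by default (the estimators assume
  mean-zero series; real data are not), with an opt-out for pre-centered
  data. Constant series raise a degenerate-input error at entry rather
  than a division error downstream.

## Standard errors

All schemes share the sandwich `se(phi) = sqrt(q⁻¹ ω q⁻¹ / n)` with
`n = T` (time domain) or `K` (ACF domain), and reach the timescale via the
delta method `se(tau) = se(phi)/(|phi| log²|phi|)` (NaN at the undefined
points `phi = 0`, `|phi| >= 1`).

* **Time domain.** Scores `s_t = x_{t-1}(x_t - phi x_{t-1})`,
  `q = (1/T) Σ x_{t-1}²`. Newey-West: `ω` is the Bartlett-weighted sum of
  score autocovariances up to bandwidth `M`, with weights
  `w_l = 1 - l/(M+1)` and boundary-truncated cross sums (no padding).
  Naive: `ω = σ̂² q` with `σ̂²` the mean squared residual, recovering the
  classical `sqrt((1-phi²)/T)` for a true AR(1).
* **ACF domain.** Linearized scores `s_k = k phi^{k-1} (rho_k - phi^k)`,
  `q = (1/K) Σ (k phi^{k-1})²`; same Bartlett construction over lags.
* **Hybrid.** The decay estimate comes from the ACF-domain fit but
  residuals — and the Newey-West variance — are formed in the time domain
  (`e_t = x_t - phi_NLS x_{t-1}`): sample ACFs of autoregressive processes
  are not signal-plus-noise objects, so ACF-domain scores understate the
  true sampling variability there.

**Scaling note.** The sandwich is reported as a standard error with the
square root and the `1/n` factor; the score-sum divisors use `1/T`
(resp. `1/K`) even though one fewer score exists, an asymptotically
immaterial normalization kept for definiteness. With this scaling the
time-domain Newey-West SE agrees with the HAC covariance of the
corresponding no-intercept regression in statsmodels to machine precision
(the normalizations cancel in the sandwich), which the test suite uses as
an independent oracle.

**Bandwidth.** Default `M = floor(4 (n/100)^{2/9})` — the standard
automatic Bartlett rule (`M = 9` at `n = 4800`); any explicit `M`
overrides it.

### Known limitations of the SE schemes

These are properties of the estimators, reproduced by the package's own
Monte Carlo harness; they matter when interpreting results.

* *ACF-domain Newey-West window collapse.* At the NLS minimum the score
  sum `Σ_k s_k` is exactly zero (first-order condition), and the scores
  are concentrated on roughly `tau` lags because `k phi^{k-1}` decays.
  When the Bartlett window is comparable to that support, the weighted sum
  nearly annihilates `ω`, biasing the SE toward zero even under iid ACF
  errors. The iid-error agreement between naive and Newey-West ACF-domain
  SEs therefore holds only for bandwidths well below the score support
  (the suite demonstrates agreement at `phi = 0.9`, `M <= 2`).
* *Hybrid SE understates the ACF-domain spread at strong autocorrelation.*
  The time-domain sandwich consistently estimates the sampling variance of
  the time-domain projection. The ACF-domain estimator, pooling many
  positively correlated sample-ACF lags, has strictly larger sampling
  variance at large `phi` (its SD is roughly 1.7x the time-domain SD at
  `phi = 0.8` for `T = 4800`). The hybrid SE, being a time-domain
  sandwich, tracks the smaller of the two: its relative RMSE against the
  across-replication SD of the ACF-domain timescale grows from ~5% at
  `phi = 0.1` to ~40% at `phi = 0.8` in the package's own study
  (`scripts/acceptance.py`, target `t2`). Where this matters, the
  time-domain estimator with its own Newey-West SE is the calibrated
  choice — consistent with its z-scores having unit SD in the suite's
  calibration check.

## Synthetic data and the Monte Carlo design

Generators produce data with an analytically known AR(1) projection
`phi*` so recovery can be scored against ground truth:

* **AR(1)** `x_t = phi x_{t-1} + e_t`, iid Gaussian innovations,
  initialized exactly at the stationary distribution (no burn-in).
* **AR(2)** `x_t = phi1 x_{t-1} + phi2 x_{t-2} + e_t`, restricted to the
  stationary triangle and the aperiodic region `phi2 >= -phi1²/4`;
  1000-sample burn-in from zero initial conditions. `ar2_design` solves
  the matching problem `phi1 = phi*(1 - phi2)` so that the AR(1)
  projection (`rho_1 = phi1/(1-phi2)`) hits a requested `phi*`; the
  default second coefficient is 0.2, inside the admissible region for the
  whole `phi*` grid.
* **Arbitrary-ACF Gaussian process** `x = L e` with `L L' = Σ` the
  Toeplitz correlation matrix of a target ACF (Cholesky; escalating
  diagonal jitter `1e-8 .. 1e-4` before failing). This emulates empirical
  (e.g. fMRI-derived) autocorrelation structure from any user-supplied
  ACF vector.
* **Noisy ACF curves** `rho_k = signal_k + e_k` with iid Gaussian noise at
  every lag including `k = 0`; the AR(2) variant injects the noise into
  the Yule-Walker recursion itself (each noisy value feeds the next lag,
  seeded with `rho_0 = 1`, `rho_1 = phi1/(1-phi2)` before noise). These
  isolate the curve-fitting step of the two-step ACF-domain method from
  sample-ACF estimation error. The default noise SD of 1 reproduces the
  printed design but is enormous relative to a curve bounded by 1: with
  it the objective's curvature supports only SD(phi-hat) of about 0.5,
  and boundary clipping biases the fit — so the estimator is *not* in its
  asymptotic regime there. Property tests of unbiasedness and SE recovery
  use a configurable noise SD of 0.05, where it is.

The evaluation grid uses five coefficients evenly spanning 0.1–0.8
(`{0.1, 0.275, 0.45, 0.625, 0.8}`), the range of time-domain estimates
observed in resting-state fMRI, at `T = 4800` timepoints. Estimator
quality is relative RMSE against the true timescale; SE quality is
relative RMSE against the across-replication SD of the estimates. Each
(setting, replication) pair gets an independent RNG stream spawned
deterministically from the master seed, so results are independent of
execution order; failed replications are counted and excluded, never
silently dropped.

What the generators do *not* emulate: measurement noise on top of the
process, scanner drift or motion artifacts, non-stationarity, spatial
correlation between vertices, and run-concatenation effects. Passing
recovery tests therefore demonstrates correctness of the estimators under
their stated assumptions, not robustness to every failure mode of real
acquisitions.

## Group-level maps

Per-subject fits (each column of a timepoints × vertices matrix fit
independently; degenerate columns flagged, not fatal) are combined per
vertex as `tau_bar = mean(tau_n)` and, by the law of total variance,

```
se_group = sqrt( mean(se_n²) + mean((tau_n - tau_bar)²) )
```

As written this is the total SD of a *single subject's* estimate. Whether
the between/within bracket should additionally be divided by `N` to give
the standard error of the group mean is genuinely ambiguous in the field's
usage; the package implements the unscaled form by default and exposes
`scale_by_n=True` for the SE-of-the-mean convention, surfacing the choice
instead of resolving it silently. Both variance components are kept on the
result for audit. Subjects with non-finite estimates at a vertex are
dropped there with the retained count reported; all combination happens in
seconds, so subjects may differ in sampling interval. t-statistics test
`H0: tau <= tau_0` (default 0.5 s) as `(tau_bar - tau_0)/se_group`;
relative SEs are `se_group/tau_bar`. Zero-SE vertices yield `t = 0` at the
threshold and signed infinity otherwise; `rse` is masked where the mean is
zero. No multiple-comparison correction is applied — maps are reported
unthresholded.

## Problem sizes

The shipped study sizes balance Monte Carlo precision against desk-scale
runtimes: 1000 replications per setting for timescale recovery (the
closed-form estimator is vectorized across replications), 500 for the
hybrid-SE study (each replication fits the NLS to a `K = 4799` sample
ACF), and a 30-subject × 500-vertex synthetic cohort for the group
pipeline. All are package choices and scale up linearly via the public
API.
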