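# timescales

Timescale estimation for stationary time series, with honest uncertainty.

Neural activity decorrelates at characteristic rates: sensory cortex
fluctuates quickly, association cortex slowly. Mapping these *intrinsic
timescales* — for example vertex-by-vertex over the cortical surface from
resting-state fMRI — requires estimating, for thousands of series at once,
how fast the autocorrelation function (ACF) decays, and attaching standard
errors so that maps of estimates can support actual inference rather than
point-estimate comparisons.

This package implements two projection-based timescale estimators, three
standard-error schemes that remain valid when the fitted model is not the
data-generating process, a synthetic-data and Monte Carlo evaluation
suite, and group-level map inference.

## The model

For a weakly stationary, strong-mixing process `X_t` with autocorrelation
`rho_k`, the timescale `tau` is the (real-valued) lag at which the best
exponentially decaying approximation of the ACF reaches `1/e`:

```
rho_k ≈ phi^k,    tau = g(phi) = -1 / log|phi|,    |phi|^tau = 1/e
```

Two projections define `phi`:

* **Time domain (LLS)** — the no-intercept least-squares slope of `x_t` on
  `x_{t-1}`, in closed form
  `phi = (Σ x_{t-1}²)⁻¹ Σ x_t x_{t-1}`. This is the AR(1) *projection*:
  the process need not be AR(1); deviations go into the error term.
* **Autocorrelation domain (NLS)** — Levenberg-Marquardt least squares of
  `phi^k` to the sample ACF
  `rho_k = (Σ x_t²)⁻¹ Σ_{t=k+1} x_t x_{t-k}` over lags `k = 0..K`,
  capturing decay across many lags at once.

Standard errors take the sandwich form `se(phi) = sqrt(q⁻¹ ω q⁻¹ / n)`
with `q` the curvature of the squared loss and `ω` the long-run variance
of the regression scores, estimated by a Bartlett-kernel (Newey-West) sum
up to a bandwidth `M` — consistent under heteroskedastic, autocorrelated
projection errors. Naive (iid-error) variants are included for comparison,
and a **hybrid** scheme computes the SE of the ACF-domain estimate from
time-domain residuals, because sample ACFs of autoregressive processes are
not signal-plus-noise objects. All SEs propagate to the timescale by the
delta method, `se(tau) = se(phi) / (|phi| log²|phi|)`.

Group-level maps combine per-subject timescales by the law of total
variance (within-subject sampling variance + between-subject dispersion)
into mean maps, t-statistic maps against a threshold (default
`H0: tau ≤ 0.5 s`), and relative-SE precision maps.

## Worked example

```
$ python examples/fit_single_series.py
true decay phi = 0.6, true timescale = 1.409 s
LLS (time domain): phi = 0.6130, tau = 1.471 s +- 0.053 (se: newey_west, M = 9)
NLS (ACF domain) : phi = 0.6247, tau = 1.530 s +- 0.055 (se: hybrid, M = 9)
```

One simulated AR(1) series (`phi = 0.6`, `T = 4800`, TR = 0.72 s) has a
true timescale of 1.41 s. Both estimators land within about two standard
errors of the truth; the reported `+-` is the Newey-West (resp. hybrid)
standard error in seconds, and `M` is the automatic Bartlett bandwidth.
`examples/monte_carlo_recovery.py` repeats this over a grid of decay rates
and prints relative RMSEs; `examples/group_level_maps.py` runs the full
mass-univariate + group pipeline on a synthetic cohort.

## Command line

The same functionality is exposed as a thin CLI for TSV matrices
(rows = timepoints, columns = series/vertices):

```
timescales fit --input X.tsv --method lls --se nw --tr 0.72 --output fits.tsv
timescales simulate --model ar1 --phi 0.8 --T 4800 --N 100 --seed 1 --output sim.tsv
timescales group --inputs subject_fits/ --threshold 0.5 --output group.tsv
```

Every output table carries a JSON sidecar with the full configuration and
seed; identical seeds give byte-identical outputs.

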