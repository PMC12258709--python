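"""Timescale estimators for stationary time series.

Two routes to the same quantity — the e-folding time of autocorrelation
decay — are implemented here:

* a **time-domain linear projection**: ordinary least squares of ``x_t`` on
  ``x_{t-1}`` without intercept, whose coefficient is the lag-1
  autocorrelation of the best AR(1) approximation of the process
  (:func:`fit_lls`);
* an **autocorrelation-domain nonlinear fit**: Levenberg-Marquardt least
  squares of an exponential decay ``phi**k`` to the sample ACF across many
  lags (:func:`fit_nls`).

Neither route assumes the data actually follow an AR(1) or an exponential
ACF; the fitted ``phi`` is a projection parameter, well defined for any
stationary mixing process.  The timescale is the change of variable
``tau = -1 / log|phi|``, the (real-valued) lag at which the fitted
exponential ACF reaches ``1/e``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Union

import numpy as np
from scipy.fft import next_fast_len, irfft, rfft
from scipy.optimize import least_squares

from .exceptions import DegenerateInputError, InvalidLagError

__all__ = [
    "TimeSeriesSample",
    "AcfSample",
    "TimescaleFit",
    "FitConfig",
    "center_series",
    "sample_acf",
    "fit_lls",
    "fit_nls",
    "phi_to_tau",
    "tau_se_delta",
    "phi_power",
]

# boundary beyond which a decay estimate is treated as non-stationary
_PHI_CLIP = 1.0 - 1e-8


@dataclass(frozen=True)
class TimeSeriesSample:
    """An observed series ``x_1 .. x_T`` with its sampling interval.

    Parameters
    ----------
    values
        The signal, arbitrary units, length ``T >= 3``, all finite.
    sampling_interval
        Seconds per timepoint (the TR for fMRI), used only to convert
        timescales from lag units to seconds.  Default 1.0.
    centered
        Whether the sample mean has already been removed.
    """

    values: np.ndarray
    sampling_interval: float = 1.0
    centered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if values.size < 3:
            raise ValueError(f"need T >= 3 timepoints, got T={values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must all be finite")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AcfSample:
    """Sample (or synthetic) autocorrelations ``rho_0 .. rho_K``.

    ``values[k]`` is the autocorrelation at lag ``k``; ``max_lag`` is ``K``.
    ``source_length`` records the length of the originating series when the
    ACF was computed from data, and is ``None`` for synthetic curves.  ACFs
    computed from data satisfy ``rho_0 == 1`` and ``|rho_k| <= 1``; synthetic
    noisy curves may violate both and are accepted as-is.
    """

    values: np.ndarray
    max_lag: int
    source_length: Optional[int] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("ACF values must be one-dimensional")
        if values.size != self.max_lag + 1:
            raise ValueError(
                f"expected {self.max_lag + 1} values for max_lag={self.max_lag}, "
                f"got {values.size}"
            )
        if self.max_lag < 1:
            raise InvalidLagError("need at least one lag beyond lag 0")


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by the fitting routines.

    ``max_lag`` is the number of ACF lags ``K`` used by the nonlinear fit
    ("all" means ``K = T - 1``).  ``bandwidth`` is the Newey-West lag
    truncation ``M`` ("auto" selects ``floor(4 * (T/100)**(2/9))``).
    ``tolerance`` is the Levenberg-Marquardt step-size stopping threshold.
    """

    method: Literal["lls", "nls"] = "lls"
    se_method: Literal["naive", "newey_west", "hybrid"] = "newey_west"
    max_lag: Union[int, Literal["all"]] = "all"
    bandwidth: Union[int, Literal["auto"]] = "auto"
    tolerance: float = 1e-6
    max_iterations: int = 1000
    center: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_lag != "all" and self.max_lag < 1:
            raise ValueError("max_lag must be >= 1 or 'all'")
        if self.bandwidth != "auto" and self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0 or 'auto'")
        if self.method not in ("lls", "nls"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.se_method not in ("naive", "newey_west", "hybrid"):
            raise ValueError(f"unknown se_method {self.se_method!r}")


@dataclass
class TimescaleFit:
    """The result of a timescale fit: decay parameter, timescale, errors.

    ``flags`` may contain ``"nondecaying"`` (``|phi| >= 1``, timescale
    infinite), ``"nonstationary_estimate"`` (the optimizer left the open
    unit interval and the estimate was clipped back), and
    ``"degenerate_input"`` (the input carried no signal).
    """

    phi: float
    tau_lags: float
    tau_seconds: float
    se_phi: float = math.nan
    se_tau_lags: float = math.nan
    se_tau_seconds: float = math.nan
    fit_domain: Literal["time", "autocorrelation"] = "time"
    se_method: Literal["naive", "newey_west", "hybrid", "none"] = "none"
    bandwidth: Optional[int] = None
    n_lags: Optional[int] = None
    converged: bool = True
    n_iterations: int = 0
    objective: float = math.nan
    flags: frozenset = field(default_factory=frozenset)

    def with_se(
        self,
        se_phi: float,
        se_tau_lags: float,
        sampling_interval: float,
        se_method: str,
        bandwidth: Optional[int] = None,
    ) -> "TimescaleFit":
        """Return a copy with standard errors attached."""
        return replace(
            self,
            se_phi=se_phi,
            se_tau_lags=se_tau_lags,
            se_tau_seconds=se_tau_lags * sampling_interval,
            se_method=se_method,
            bandwidth=bandwidth,
        )


def phi_power(phi: float, k: np.ndarray) -> np.ndarray:
    """``phi**k`` for integer lags ``k >= 0``, valid for negative ``phi``.

    Uses ``sign(phi)**k * |phi|**k`` so that a negative base never meets a
    float exponent; ``0**0`` is 1 by the usual convention.
    """
    k = np.asarray(k)
    return np.sign(phi) ** k * np.abs(phi) ** k


def center_series(x: TimeSeriesSample) -> TimeSeriesSample:
    """Remove the sample mean; idempotent on already-centered input."""
    values = x.values - x.values.mean()
    if np.all(values == 0.0):
        raise DegenerateInputError("series is constant: zero variance")
    return TimeSeriesSample(
        values=values, sampling_interval=x.sampling_interval, centered=True
    )


def sample_acf(x: TimeSeriesSample, max_lag: int) -> AcfSample:
    """Sample autocorrelation function up to lag ``K = max_lag``.

    Implements the lag-scaled estimator
    ``rho_k = sum_{t=k+1}^{T} x_t x_{t-k} / sum_{t=1}^{T} x_t**2``:
    the lag-``k`` cross-sum (``T - k`` terms) is divided by the full-sample
    sum of squares, which shrinks high-lag estimates toward zero and bounds
    ``|rho_k| <= 1``.  Computed via FFT, identical to the direct double sum
    to floating-point round-off.
    """
    values = x.values
    T = values.size
    if not x.centered:
        raise ValueError("sample_acf expects a centered series; use center_series")
    if max_lag >= T:
        raise InvalidLagError(f"max_lag must be < T={T}, got {max_lag}")
    if max_lag < 1:
        raise InvalidLagError("max_lag must be >= 1")

    denom = float(values @ values)
    if denom == 0.0:
        raise DegenerateInputError("series has zero variance")

    n = next_fast_len(2 * T)
    spectrum = rfft(values, n)
    autocov = irfft(spectrum * np.conj(spectrum), n)[: max_lag + 1]
    rho = autocov / denom
    rho[0] = 1.0  # exact by construction
    return AcfSample(values=rho, max_lag=max_lag, source_length=T)


def phi_to_tau(phi: float) -> float:
    """Timescale (in lag units) of the exponential ACF with decay ``phi``.

    ``tau = -1 / log|phi|`` is the real-valued lag at which ``|phi|**tau``
    reaches ``1/e``.  By the limit convention ``tau = 0`` at ``phi = 0``;
    ``|phi| >= 1`` yields ``+inf`` (a non-decaying fit).
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    a = abs(phi)
    if a == 0.0:
        return 0.0
    if a >= 1.0:
        return math.inf
    return -1.0 / math.log(a)


def tau_se_delta(se_phi: float, phi: float) -> float:
    """Delta-method standard error of ``tau`` from the one of ``phi``.

    ``se_tau = se_phi * |g'(phi)|`` with ``g(phi) = -1/log|phi|`` and
    ``|g'(phi)| = 1 / (|phi| * log(|phi|)**2)``.  Undefined at ``phi = 0``
    and for ``|phi| >= 1``; returns NaN there so mass-univariate runs
    continue.
    """
    if se_phi < 0:
        raise ValueError("se_phi must be non-negative")
    a = abs(phi)
    if a == 0.0 or a >= 1.0 or not np.isfinite(phi):
        return math.nan
    return se_phi / (a * math.log(a) ** 2)


def _finalize_phi(phi: float) -> tuple[float, frozenset]:
    """Map a raw decay estimate to (phi, flags), clipping at the unit circle."""
    flags = set()
    if abs(phi) >= 1.0:
        flags.add("nondecaying")
    return phi, frozenset(flags)


def fit_lls(x: TimeSeriesSample) -> TimescaleFit:
    """Closed-form time-domain AR(1) projection estimate.

    ``phi = sum_{t=2}^{T} x_t x_{t-1} / sum_{t=2}^{T} x_{t-1}**2`` — the
    no-intercept least-squares slope of ``x_t`` on its own past.  No
    standard error is attached; that is a separate pass
    (see :mod:`timescales.standard_errors`).
    """
    values = x.values
    lagged = values[:-1]
    denom = float(lagged @ lagged)
    if denom == 0.0:
        raise DegenerateInputError("zero lagged variance")
    phi = float(values[1:] @ lagged) / denom
    phi, flags = _finalize_phi(phi)
    tau = phi_to_tau(phi)
    return TimescaleFit(
        phi=phi,
        tau_lags=tau,
        tau_seconds=tau * x.sampling_interval,
        fit_domain="time",
        flags=flags,
    )


_START_GRID = np.arange(-0.999, 0.9995, 1e-3)


def _best_start(rho: np.ndarray, K: int, moment_start: float) -> float:
    """Best Levenberg-Marquardt starting value among the lag-1 moment
    start and a fixed 1e-3 grid over (-0.999, 0.999).

    The grid objective is evaluated in closed form:
    ``K * S(phi) = sum rho_k**2 - 2 * sum rho_k phi**k + sum phi**(2k)``,
    where the cross term is a polynomial in ``phi`` (Horner evaluation) and
    the last term is a finite geometric sum.
    """
    candidates = np.append(_START_GRID, moment_start)
    cross = np.polynomial.polynomial.polyval(candidates, rho)
    g2 = candidates**2
    with np.errstate(under="ignore"):
        pow_sum = (1.0 - g2 ** (K + 1)) / (1.0 - g2)
    objective = -2.0 * cross + pow_sum  # constant sum(rho**2) omitted
    return float(candidates[int(np.argmin(objective))])


def fit_nls(
    acf: AcfSample,
    config: FitConfig = FitConfig(method="nls"),
    sampling_interval: float = 1.0,
) -> TimescaleFit:
    """Exponential-decay fit to an ACF by Levenberg-Marquardt least squares.

    Minimizes ``S(phi) = (1/K) * sum_{k=0}^{K} (rho_k - phi**k)**2`` over
    the decay parameter, iterating until the step size falls below
    ``config.tolerance``.  The lag-0 residual is identically zero and its
    score derivative is defined as zero; both are kept in the sums.

    ``S`` is a high-degree polynomial in ``phi`` and can have several local
    minima on noisy curves, so the Levenberg-Marquardt iteration is started
    from the best of (a) the lag-1 autocorrelation (the natural moment
    start, clipped to ``+-0.999``) and (b) a 1e-3 grid over
    ``(-0.999, 0.999)`` evaluated in closed form; the polish step can only
    decrease the objective, so the returned estimate dominates the whole
    grid.  An estimate outside the open unit interval is clipped back to it
    and flagged ``nonstationary_estimate``.
    """
    rho = acf.values
    K = acf.max_lag
    k = np.arange(K + 1)
    sqrt_k = math.sqrt(K)
    _BIG = 1e100  # caps overflow when the optimizer probes |phi| > 1

    def residuals(params: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            r = (rho - phi_power(params[0], k)) / sqrt_k
        return np.nan_to_num(r, nan=_BIG, posinf=_BIG, neginf=-_BIG)

    def jacobian(params: np.ndarray) -> np.ndarray:
        phi = params[0]
        deriv = np.zeros(K + 1)
        with np.errstate(over="ignore", invalid="ignore"):
            deriv[1:] = k[1:] * phi_power(phi, k[1:] - 1)
        deriv = np.nan_to_num(deriv, nan=_BIG, posinf=_BIG, neginf=-_BIG)
        return (-deriv / sqrt_k)[:, None]

    phi0 = _best_start(rho, K, float(np.clip(rho[1], -0.999, 0.999)))
    result = least_squares(
        residuals,
        x0=[phi0],
        jac=jacobian,
        method="lm",
        xtol=config.tolerance,
        ftol=np.finfo(float).eps,
        gtol=np.finfo(float).eps,
        max_nfev=config.max_iterations,
    )
    phi = float(result.x[0])

    flags = set()
    if abs(phi) >= _PHI_CLIP:
        # clip back inside the open unit interval so tau stays finite
        flags.add("nonstationary_estimate")
        phi = float(np.clip(phi, -_PHI_CLIP, _PHI_CLIP))
    converged = bool(result.status > 0)
    if not converged:
        warnings.warn(
            f"nonlinear fit did not converge in {config.max_iterations} evaluations",
            RuntimeWarning,
            stacklevel=2,
        )
    objective = float(np.sum((rho - phi_power(phi, k)) ** 2) / K)
    tau = phi_to_tau(phi)
    return TimescaleFit(
        phi=phi,
        tau_lags=tau,
        tau_seconds=tau * sampling_interval,
        fit_domain="autocorrelation",
        n_lags=K,
        converged=converged,
        n_iterations=int(result.nfev),
        objective=objective,
        flags=frozenset(flags),
    )
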