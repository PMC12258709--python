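"""Naive and Newey-West standard errors for timescale estimators.

Both estimators (time-domain linear projection, autocorrelation-domain
exponential fit) admit a sandwich-form asymptotic variance
``q^-1 * omega * q^-1`` where ``q`` is the curvature of the squared loss at
its minimum and ``omega`` the long-run variance of the regression scores.
The Newey-West estimator of ``omega`` sums Bartlett-kernel-weighted score
autocovariances up to a lag truncation (bandwidth) ``M``, making the
standard errors consistent under heteroskedasticity and autocorrelation of
the projection errors — i.e. under model misspecification.  The naive
variants assume iid errors and reduce to the classical formulas.

Standard errors of ``phi`` are scaled as ``sqrt(q^-1 omega q^-1 / n)``
(``n = T`` or ``K``) and propagated to the timescale by the delta method.

The **hybrid** scheme addresses a subtlety of the autocorrelation-domain
fit: the sample ACF of an autoregressive process is not a signal-plus-noise
object, so score-based errors computed in the ACF domain are badly
downward-biased there.  The hybrid takes the decay estimate from the ACF
fit but forms residuals — and the Newey-West variance — in the time domain.
"""

from __future__ import annotations

import math

import numpy as np

from .estimators import (
    AcfSample,
    TimeSeriesSample,
    phi_power,
    tau_se_delta,
)
from .exceptions import InvalidLagError

__all__ = [
    "default_bandwidth",
    "bartlett_weights",
    "nw_se_time",
    "naive_se_time",
    "nw_se_acf",
    "naive_se_acf",
    "hybrid_se",
]


def default_bandwidth(n: int) -> int:
    """Automatic Bartlett bandwidth ``M = floor(4 * (n/100)**(2/9))``.

    The standard plug-in rule for the Bartlett kernel; grows slowly and
    monotonically with the sample size (``M = 4`` at ``n = 100``, ``M = 9``
    at ``n = 4800``).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    return int(math.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def bartlett_weights(M: int) -> np.ndarray:
    """Bartlett kernel weights ``w_l = 1 - l/(M+1)`` for ``l = 0..M``."""
    if M < 0:
        raise ValueError("bandwidth must be >= 0")
    return 1.0 - np.arange(M + 1) / (M + 1.0)


def _long_run_variance(scores: np.ndarray, M: int, norm: int) -> float:
    """Bartlett-weighted long-run variance of a score series.

    ``omega = w_0 c_0 + 2 * sum_{l=1}^{M} w_l c_l`` with
    ``c_l = (1/norm) * sum_t s_t s_{t-l}``; cross-lag sums truncate at the
    data boundary (no padding or wrap-around).  The symmetric Bartlett
    construction keeps the result non-negative.
    """
    weights = bartlett_weights(M)
    omega = float(scores @ scores)
    for lag in range(1, min(M, scores.size - 1) + 1):
        omega += 2.0 * weights[lag] * float(scores[lag:] @ scores[:-lag])
    return omega / norm


def _time_domain_components(
    x: TimeSeriesSample, phi: float
) -> tuple[np.ndarray, float, int]:
    """Scores ``s_t = x_{t-1} * e_t``, curvature ``q``, and ``T``."""
    values = x.values
    T = values.size
    lagged = values[:-1]
    residuals = values[1:] - phi * lagged
    scores = lagged * residuals
    q = float(lagged @ lagged) / T
    return scores, q, T


def nw_se_time(
    x: TimeSeriesSample, phi: float, M: int
) -> tuple[float, float]:
    """Newey-West standard errors of the time-domain decay and timescale.

    Returns ``(se_phi, se_tau)`` in lag units.  ``se_phi =
    sqrt(q^-1 omega q^-1 / T)`` with ``q = (1/T) sum x_{t-1}**2`` and
    ``omega`` the Bartlett-weighted long-run variance of the regression
    scores ``x_{t-1} * (x_t - phi x_{t-1})``.
    """
    if not x.centered:
        raise ValueError("standard errors expect a centered series")
    T = x.n_timepoints
    if not 0 <= M <= T - 2:
        raise ValueError(f"bandwidth must satisfy 0 <= M <= T-2, got M={M}")
    scores, q, T = _time_domain_components(x, phi)
    omega = _long_run_variance(scores, M, norm=T)
    variance = max(omega / (q * q * T), 0.0)
    se_phi = math.sqrt(variance)
    return se_phi, tau_se_delta(se_phi, phi)


def naive_se_time(x: TimeSeriesSample, phi: float) -> tuple[float, float]:
    """Classical iid-error standard errors for the time-domain fit.

    ``se_phi = sqrt(sigma2 q^-1 / T)`` with ``sigma2 = (1/T) sum e_t**2``.
    For a correctly specified AR(1) this approaches
    ``sqrt((1 - phi**2)/T)``; under misspecification it is downward-biased.
    """
    if not x.centered:
        raise ValueError("standard errors expect a centered series")
    values = x.values
    T = values.size
    lagged = values[:-1]
    residuals = values[1:] - phi * lagged
    sigma2 = float(residuals @ residuals) / T
    q = float(lagged @ lagged) / T
    se_phi = math.sqrt(sigma2 / (q * T))
    return se_phi, tau_se_delta(se_phi, phi)


def _acf_domain_components(
    acf: AcfSample, phi: float
) -> tuple[np.ndarray, float, int]:
    """Linearized scores ``s_k = m_k * e_k``, curvature ``q``, and ``K``."""
    rho = acf.values
    K = acf.max_lag
    k = np.arange(K + 1)
    m = np.zeros(K + 1)
    m[1:] = k[1:] * phi_power(phi, k[1:] - 1)  # d(phi**k)/dphi; zero at k=0
    residuals = rho - phi_power(phi, k)
    scores = m * residuals
    q = float(m @ m) / K
    return scores, q, K


def nw_se_acf(acf: AcfSample, phi: float, M: int) -> tuple[float, float]:
    """Newey-West standard errors in the autocorrelation domain.

    Scores are the linearized regression scores ``k phi**(k-1) *
    (rho_k - phi**k)`` over lags ``k = 0..K``; ``se_phi =
    sqrt(q^-1 omega q^-1 / K)``.  Appropriate when the ACF genuinely is
    signal plus noise; see :func:`hybrid_se` otherwise.
    """
    K = acf.max_lag
    if not 0 <= M <= K - 1:
        raise InvalidLagError(f"bandwidth must satisfy 0 <= M <= K-1, got M={M}")
    scores, q, K = _acf_domain_components(acf, phi)
    omega = _long_run_variance(scores, M, norm=K)
    variance = max(omega / (q * q * K), 0.0)
    se_phi = math.sqrt(variance)
    return se_phi, tau_se_delta(se_phi, phi)


def naive_se_acf(acf: AcfSample, phi: float) -> tuple[float, float]:
    """Classical iid-error standard errors for the ACF-domain fit.

    ``se_phi = sqrt(sigma2 q^-1 / K)`` with ``sigma2`` the mean squared
    ACF residual.
    """
    scores, q, K = _acf_domain_components(acf, phi)
    rho = acf.values
    k = np.arange(K + 1)
    residuals = rho - phi_power(phi, k)
    sigma2 = float(residuals @ residuals) / K
    se_phi = math.sqrt(sigma2 / (q * K))
    return se_phi, tau_se_delta(se_phi, phi)


def hybrid_se(
    x: TimeSeriesSample, phi_nls: float, M: int
) -> tuple[float, float]:
    """Hybrid autocorrelation/time-domain standard errors.

    Identical computation to :func:`nw_se_time` but with residuals formed
    from the ACF-domain decay estimate, ``e_t = x_t - phi_nls x_{t-1}``:
    the timescale is defined in the autocorrelation domain while its
    sampling variability is measured where it actually lives, in the time
    domain.
    """
    return nw_se_time(x, phi_nls, M)
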