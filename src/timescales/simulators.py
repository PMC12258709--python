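"""Synthetic data generators and the Monte Carlo evaluation harness.

Three time-series generators produce data whose AR(1) projection is known
analytically, so estimator recovery can be scored against ground truth:

* :func:`simulate_ar1` — the correctly specified case;
* :func:`simulate_ar2` — a second-order process (misspecified for an AR(1)
  fit), restricted to the stationary, aperiodic region;
* :func:`simulate_from_acf` — a stationary Gaussian process with an
  arbitrary target ACF, drawn via Cholesky factorization of the Toeplitz
  covariance (how empirical fMRI autocorrelation structure is emulated).

A fourth generator, :func:`simulate_noisy_acf`, produces autocorrelation
*curves* directly (signal + iid Gaussian noise), isolating the second step
of the two-step ACF-domain method from sample-ACF estimation error.

:func:`run_monte_carlo` ties generators and estimators together and scores
timescale estimates and their standard errors by relative RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz
from scipy.signal import lfilter

from .estimators import (
    AcfSample,
    FitConfig,
    TimeSeriesSample,
    center_series,
    fit_lls,
    fit_nls,
    phi_to_tau,
    sample_acf,
)
from .exceptions import PositiveDefiniteError, StationarityError
from .standard_errors import (
    default_bandwidth,
    hybrid_se,
    naive_se_acf,
    naive_se_time,
    nw_se_acf,
    nw_se_time,
)

__all__ = [
    "Ar1Spec",
    "Ar2Spec",
    "AcfTarget",
    "NoisyAcfSpec",
    "SimulationSetting",
    "DEFAULT_PHI_GRID",
    "simulate_ar1",
    "simulate_ar2",
    "ar2_design",
    "ar2_acf",
    "simulate_from_acf",
    "simulate_noisy_acf",
    "run_monte_carlo",
    "rrmse",
]

# Five autocorrelation strengths evenly spanning the range observed in
# resting-state fMRI (AR1-projection estimates between +0.1 and +0.8).
DEFAULT_PHI_GRID: tuple[float, ...] = (0.1, 0.275, 0.45, 0.625, 0.8)

_AR2_BURN_IN = 1000


@dataclass(frozen=True)
class Ar1Spec:
    """First-order autoregressive generator ``x_t = phi x_{t-1} + e_t``."""

    phi: float
    T: int
    noise_sd: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(self.phi) >= 1.0:
            raise StationarityError(f"|phi| must be < 1, got {self.phi}")
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def lag1_autocorrelation(self) -> float:
        return self.phi


@dataclass(frozen=True)
class Ar2Spec:
    """Second-order autoregressive generator, stationary and aperiodic.

    Stationarity requires ``phi2 > -1``, ``phi1 + phi2 < 1`` and
    ``phi2 - phi1 < 1`` (the AR(2) triangle); aperiodicity additionally
    requires real characteristic roots, ``phi2 >= -phi1**2 / 4``.
    """

    phi1: float
    phi2: float
    T: int
    noise_sd: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.phi2 > -1.0):
            raise StationarityError("stationarity requires phi2 > -1")
        if not (self.phi1 + self.phi2 < 1.0):
            raise StationarityError("stationarity requires phi1 + phi2 < 1")
        if not (self.phi2 - self.phi1 < 1.0):
            raise StationarityError("stationarity requires phi2 - phi1 < 1")
        if self.phi2 < -self.phi1**2 / 4.0:
            raise StationarityError(
                "periodic regime (phi2 < -phi1**2/4) is not supported"
            )
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def lag1_autocorrelation(self) -> float:
        # Yule-Walker: rho_1 = phi1 / (1 - phi2)
        return self.phi1 / (1.0 - self.phi2)


@dataclass(frozen=True)
class AcfTarget:
    """A target autocorrelation sequence ``rho_0 .. rho_{K-1}`` to emulate."""

    rho: np.ndarray
    label: str = "user"

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if rho.ndim != 1 or rho.size < 2:
            raise ValueError("rho must be a vector with at least two lags")
        if rho[0] != 1.0:
            raise ValueError("rho_0 must equal 1")
        if np.any(np.abs(rho) > 1.0):
            raise ValueError("|rho_k| must be <= 1")

    @property
    def lag1_autocorrelation(self) -> float:
        return float(self.rho[1])


@dataclass(frozen=True)
class NoisyAcfSpec:
    """Directly generated ACF curves: signal + iid Gaussian noise.

    ``kind="ar1"``: ``rho_k = phi**k + e_k``.
    ``kind="ar2"``: noise enters the Yule-Walker recursion itself,
    ``rho_k = phi1 rho_{k-1} + phi2 rho_{k-2} + e_k``.
    ``kind="empirical"``: ``rho_k = rho_target_k + e_k`` for a given curve.
    ``e_k ~ iid N(0, noise_sd**2)`` at every lag including ``k = 0``.
    """

    kind: str
    K: int
    phi: Optional[float] = None
    phi1: Optional[float] = None
    phi2: Optional[float] = None
    rho: Optional[np.ndarray] = None
    noise_sd: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.kind == "ar1":
            if self.phi is None or abs(self.phi) >= 1.0:
                raise ValueError("ar1 kind needs |phi| < 1")
        elif self.kind == "ar2":
            if self.phi1 is None or self.phi2 is None:
                raise ValueError("ar2 kind needs phi1 and phi2")
        elif self.kind == "empirical":
            if self.rho is None:
                raise ValueError("empirical kind needs a rho vector")
            rho = np.asarray(self.rho, dtype=float)
            object.__setattr__(self, "rho", rho)
            if rho.size < self.K + 1:
                raise ValueError("rho must cover lags 0..K")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def lag1_autocorrelation(self) -> float:
        if self.kind == "ar1":
            return float(self.phi)
        if self.kind == "ar2":
            return self.phi1 / (1.0 - self.phi2)
        return float(self.rho[1])


GeneratorSpec = Union[Ar1Spec, Ar2Spec, AcfTarget, NoisyAcfSpec]


@dataclass(frozen=True)
class SimulationSetting:
    """A generator together with its true AR(1) projection ``phi*``.

    ``phi_star`` must equal the generator's analytic lag-1 autocorrelation
    (the AR(1)-projection coefficient of any stationary process);
    ``tau_star`` is the implied true timescale in lag units.
    """

    generator: GeneratorSpec
    phi_star: float
    tau_star: float = field(init=False)
    label: str = ""

    def __post_init__(self) -> None:
        analytic = self.generator.lag1_autocorrelation
        if not math.isclose(self.phi_star, analytic, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"phi_star={self.phi_star} does not match the generator's "
                f"lag-1 autocorrelation {analytic}"
            )
        object.__setattr__(self, "tau_star", phi_to_tau(self.phi_star))


# ---------------------------------------------------------------------------
# generators


def _ar1_matrix(
    phi: float, noise_sd: float, T: int, n_series: int, rngs: Sequence[np.random.Generator]
) -> np.ndarray:
    """Stationary AR(1) draws as a (T, n_series) matrix, one RNG per column."""
    e = np.empty((T, n_series))
    x1 = np.empty(n_series)
    stationary_sd = noise_sd / math.sqrt(1.0 - phi * phi)
    for j, rng in enumerate(rngs):
        x1[j] = rng.normal(scale=stationary_sd)
        e[:, j] = rng.normal(scale=noise_sd, size=T)
    out = np.empty((T, n_series))
    out[0] = x1
    # x_t = e_t + phi * x_{t-1}; lfilter state seeds the recursion at x_1
    out[1:], _ = lfilter([1.0], [1.0, -phi], e[1:], axis=0, zi=(phi * x1)[None, :])
    return out


def simulate_ar1(spec: Ar1Spec) -> TimeSeriesSample:
    """Draw one AR(1) realization, initialized at the stationary law.

    ``x_1 ~ N(0, noise_sd**2 / (1 - phi**2))`` so no burn-in is needed;
    identical spec and seed give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    x = _ar1_matrix(spec.phi, spec.noise_sd, spec.T, 1, [rng])[:, 0]
    return TimeSeriesSample(values=x)


def _ar2_matrix(
    phi1: float, phi2: float, noise_sd: float, T: int, n_series: int,
    rngs: Sequence[np.random.Generator],
) -> np.ndarray:
    """AR(2) draws with a discarded burn-in, as a (T, n_series) matrix."""
    total = T + _AR2_BURN_IN
    e = np.empty((total, n_series))
    for j, rng in enumerate(rngs):
        e[:, j] = rng.normal(scale=noise_sd, size=total)
    x = lfilter([1.0], [1.0, -phi1, -phi2], e, axis=0)
    return x[_AR2_BURN_IN:]


def simulate_ar2(spec: Ar2Spec) -> TimeSeriesSample:
    """Draw one stationary aperiodic AR(2) realization (1000-sample burn-in)."""
    rng = np.random.default_rng(spec.seed)
    x = _ar2_matrix(spec.phi1, spec.phi2, spec.noise_sd, spec.T, 1, [rng])[:, 0]
    return TimeSeriesSample(values=x)


def ar2_acf(phi1: float, phi2: float, n_lags: int) -> np.ndarray:
    """Theoretical AR(2) ACF ``rho_0 .. rho_{n_lags}`` by the Yule-Walker
    recursion ``rho_k = phi1 rho_{k-1} + phi2 rho_{k-2}`` with
    ``rho_0 = 1`` and ``rho_1 = phi1 / (1 - phi2)``."""
    rho = np.empty(n_lags + 1)
    rho[0] = 1.0
    if n_lags >= 1:
        rho[1] = phi1 / (1.0 - phi2)
    for k in range(2, n_lags + 1):
        rho[k] = phi1 * rho[k - 1] + phi2 * rho[k - 2]
    return rho


def ar2_design(
    phi_star: float,
    phi2: float,
    T: int = 4800,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
    n_lags: Optional[int] = None,
) -> tuple[Ar2Spec, np.ndarray]:
    """AR(2) coefficients whose AR(1) projection equals ``phi_star``.

    The AR(1) projection of an AR(2) process is its lag-1 autocorrelation
    ``rho_1 = phi1 / (1 - phi2)``, so ``phi1 = phi_star * (1 - phi2)``.
    Returns the validated spec and its theoretical ACF (length
    ``n_lags + 1``, default ``T``).  Invalid combinations raise with the
    violated constraint named.
    """
    phi1 = phi_star * (1.0 - phi2)
    spec = Ar2Spec(phi1=phi1, phi2=phi2, T=T, noise_sd=noise_sd, seed=seed)
    if n_lags is None:
        n_lags = T - 1
    return spec, ar2_acf(phi1, phi2, n_lags)


def _toeplitz_cholesky(rho: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of the Toeplitz correlation matrix, with an
    escalating diagonal jitter (1e-8 up to 1e-4) if needed."""
    sigma = toeplitz(rho)
    jitter = 0.0
    while True:
        try:
            return cholesky(sigma + jitter * np.eye(sigma.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            pass
        jitter = 1e-8 if jitter == 0.0 else jitter * 10.0
        if jitter > 1e-4:
            raise PositiveDefiniteError(
                "Toeplitz correlation matrix is not positive definite even "
                "with diagonal jitter up to 1e-4"
            )


def simulate_from_acf(
    target: AcfTarget, T: int, seed: Optional[int] = None
) -> TimeSeriesSample:
    """Stationary Gaussian series with a prescribed autocorrelation target.

    Builds the ``T x T`` Toeplitz matrix ``Sigma_ij = rho_|i-j|``, factors
    it as ``L L'`` and returns ``x = L e`` with ``e`` iid standard normal.
    """
    if T > target.rho.size:
        raise ValueError(
            f"need rho_0..rho_{T - 1} for T={T}, got {target.rho.size} lags"
        )
    L = _toeplitz_cholesky(target.rho[:T])
    rng = np.random.default_rng(seed)
    x = L @ rng.standard_normal(T)
    return TimeSeriesSample(values=x)


def simulate_noisy_acf(
    spec: NoisyAcfSpec, rng: Optional[np.random.Generator] = None
) -> AcfSample:
    """Generate one noisy autocorrelation curve ``rho_0 .. rho_K``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    K = spec.K
    e = rng.normal(scale=spec.noise_sd, size=K + 1) if spec.noise_sd > 0 else np.zeros(K + 1)
    if spec.kind == "ar1":
        k = np.arange(K + 1)
        signal = np.sign(spec.phi) ** k * np.abs(spec.phi) ** k
        rho = signal + e
    elif spec.kind == "ar2":
        # noise enters the recursion: each noisy value feeds the next lag
        rho = np.empty(K + 1)
        rho[0] = 1.0 + e[0]
        rho[1] = spec.phi1 / (1.0 - spec.phi2) + e[1]
        for k in range(2, K + 1):
            rho[k] = spec.phi1 * rho[k - 1] + spec.phi2 * rho[k - 2] + e[k]
    else:  # empirical
        rho = spec.rho[: K + 1] + e
    return AcfSample(values=rho, max_lag=K, source_length=None)


# ---------------------------------------------------------------------------
# Monte Carlo harness


def rrmse(estimates: np.ndarray, truth: float) -> float:
    """Relative root mean squared error ``sqrt(mean((est - truth)**2)) / truth``."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 1:
        raise ValueError("need at least one estimate")
    if truth == 0:
        raise ValueError("rRMSE is undefined for truth = 0")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)) / truth)


def _spawn_rngs(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(child) for child in seed_seq.spawn(n)]


def _replicate_matrix(
    generator: GeneratorSpec, N: int, rngs: Sequence[np.random.Generator]
) -> np.ndarray:
    """All N replications of a time-series generator as a (T, N) matrix."""
    if isinstance(generator, Ar1Spec):
        return _ar1_matrix(generator.phi, generator.noise_sd, generator.T, N, rngs)
    if isinstance(generator, Ar2Spec):
        return _ar2_matrix(
            generator.phi1, generator.phi2, generator.noise_sd, generator.T, N, rngs
        )
    raise TypeError(f"not a time-series generator: {type(generator).__name__}")


def _fit_replication_time_series(
    x: TimeSeriesSample,
    config: FitConfig,
    estimators: Sequence[str],
) -> dict[str, float]:
    """Fit the requested estimators plus every SE variant to one series."""
    T = x.n_timepoints
    M = default_bandwidth(T) if config.bandwidth == "auto" else config.bandwidth
    out: dict[str, float] = {}
    if "lls" in estimators:
        fit = fit_lls(x)
        out["lls:tau"] = fit.tau_lags
        out["lls:se_naive"] = naive_se_time(x, fit.phi)[1]
        out["lls:se_newey_west"] = nw_se_time(x, fit.phi, M)[1]
    if "nls" in estimators:
        K = T - 1 if config.max_lag == "all" else min(config.max_lag, T - 1)
        acf = sample_acf(x, K)
        fit = fit_nls(acf, config)
        out["nls:tau"] = fit.tau_lags
        M_acf = default_bandwidth(K) if config.bandwidth == "auto" else config.bandwidth
        out["nls:se_naive"] = naive_se_acf(acf, fit.phi)[1]
        out["nls:se_newey_west"] = nw_se_acf(acf, fit.phi, M_acf)[1]
        out["nls:se_hybrid"] = hybrid_se(x, fit.phi, M)[1]
    return out


def run_monte_carlo(
    settings: Sequence[SimulationSetting],
    N: int,
    config: FitConfig = FitConfig(),
    seed: Optional[int] = None,
    estimators: Sequence[str] = ("lls", "nls"),
) -> pd.DataFrame:
    """Monte Carlo parameter-recovery study across simulation settings.

    For each setting, ``N`` replications are generated (one independent
    random stream per replication, spawned deterministically from the
    master seed so results do not depend on execution order), the requested
    estimators and all applicable standard-error variants are fit, and
    timescale estimates and SEs are scored by relative RMSE — estimates
    against the setting's true timescale ``tau_star``, SEs against the
    empirical across-replication standard deviation of the estimates.

    Returns a tidy DataFrame with one row per (setting, estimator,
    se_method) and columns ``label, estimator, se_method, n_reps, n_failed,
    tau_star, mean_tau, sd_tau, rrmse_tau, mean_se, rrmse_se``.
    """
    if N < 2:
        raise ValueError("need N >= 2 replications")
    master = np.random.SeedSequence(seed)
    setting_seqs = master.spawn(len(settings))
    rows = []
    for setting, seq in zip(settings, setting_seqs):
        rngs = _spawn_rngs(seq, N)
        generator = setting.generator
        records: list[dict[str, float]] = []
        n_failed = 0
        if isinstance(generator, (Ar1Spec, Ar2Spec)):
            matrix = _replicate_matrix(generator, N, rngs)
            for j in range(N):
                try:
                    x = center_series(TimeSeriesSample(values=matrix[:, j]))
                    records.append(
                        _fit_replication_time_series(x, config, estimators)
                    )
                except Exception:
                    n_failed += 1
        elif isinstance(generator, AcfTarget):
            T = generator.rho.size
            L = _toeplitz_cholesky(generator.rho)
            for rng in rngs:
                try:
                    x = center_series(
                        TimeSeriesSample(values=L @ rng.standard_normal(T))
                    )
                    records.append(
                        _fit_replication_time_series(x, config, estimators)
                    )
                except Exception:
                    n_failed += 1
        elif isinstance(generator, NoisyAcfSpec):
            # curves, not series: only the ACF-domain fit applies
            M = (
                default_bandwidth(generator.K)
                if config.bandwidth == "auto"
                else config.bandwidth
            )
            for rng in rngs:
                try:
                    acf = simulate_noisy_acf(generator, rng=rng)
                    fit = fit_nls(acf, config)
                    records.append(
                        {
                            "nls:tau": fit.tau_lags,
                            "nls:se_naive": naive_se_acf(acf, fit.phi)[1],
                            "nls:se_newey_west": nw_se_acf(acf, fit.phi, M)[1],
                        }
                    )
                except Exception:
                    n_failed += 1
        else:
            raise TypeError(f"unknown generator {type(generator).__name__}")

        frame = pd.DataFrame.from_records(records)
        for estimator in ("lls", "nls"):
            tau_col = f"{estimator}:tau"
            if tau_col not in frame:
                continue
            tau = frame[tau_col].to_numpy()
            finite = np.isfinite(tau)
            tau = tau[finite]
            sd_tau = float(np.std(tau, ddof=1))
            base = {
                "label": setting.label or f"phi*={setting.phi_star:g}",
                "estimator": estimator,
                "n_reps": int(finite.sum()),
                "n_failed": n_failed + int((~finite).sum()),
                "tau_star": setting.tau_star,
                "mean_tau": float(np.mean(tau)),
                "sd_tau": sd_tau,
                "rrmse_tau": rrmse(tau, setting.tau_star),
            }
            for se_method in ("naive", "newey_west", "hybrid"):
                col = f"{estimator}:se_{se_method}"
                if col not in frame:
                    continue
                se = frame[col].to_numpy()[finite]
                se_ok = se[np.isfinite(se)]
                rows.append(
                    {
                        **base,
                        "se_method": se_method,
                        "mean_se": float(np.mean(se_ok)),
                        "rrmse_se": rrmse(se_ok, sd_tau),
                    }
                )
    return pd.DataFrame(rows)
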