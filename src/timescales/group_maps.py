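"""Mass-univariate fitting and group-level timescale map inference.

Each column (vertex) of an input matrix is fit independently —
the mass-univariate approach of brain mapping — producing per-subject maps
of timescales and standard errors.  Subject maps are then combined into
group maps: the vertex-wise mean timescale, a combined standard error by
the law of total variance (within-subject sampling variance plus
between-subject dispersion), t-statistics against a timescale threshold,
and relative standard errors (RSE = SE / estimate, a precision map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    FitConfig,
    TimeSeriesSample,
    TimescaleFit,
    center_series,
    fit_lls,
    fit_nls,
    sample_acf,
)
from .exceptions import DegenerateInputError
from .standard_errors import (
    default_bandwidth,
    hybrid_se,
    naive_se_acf,
    naive_se_time,
    nw_se_acf,
    nw_se_time,
)

__all__ = ["SubjectFitMap", "GroupMap", "fit_series", "fit_map", "group_combine", "group_stats"]

DEFAULT_TAU_THRESHOLD_S = 0.5  # H0: tau <= 0.5 seconds


def fit_series(
    x: TimeSeriesSample, config: FitConfig = FitConfig()
) -> TimescaleFit:
    """Fit one series end to end: center, estimate, attach standard errors.

    The estimator (``lls`` time-domain or ``nls`` autocorrelation-domain)
    and standard-error scheme (``naive``, ``newey_west``, or — for the
    ACF-domain fit — ``hybrid``) come from ``config``.  Timescales and SEs
    are reported both in lag units and in seconds.
    """
    if config.center:
        x = center_series(x)
    elif not x.centered:
        raise ValueError("input must be centered when center=False")
    T = x.n_timepoints
    M = default_bandwidth(T) if config.bandwidth == "auto" else config.bandwidth

    if config.method == "lls":
        fit = fit_lls(x)
        fit = replace(fit, tau_seconds=fit.tau_lags * x.sampling_interval)
        if config.se_method == "hybrid":
            raise ValueError(
                "hybrid standard errors apply to the ACF-domain fit; "
                "use 'newey_west' for the time-domain fit"
            )
        if config.se_method == "naive":
            se_phi, se_tau = naive_se_time(x, fit.phi)
        else:
            se_phi, se_tau = nw_se_time(x, fit.phi, M)
        bandwidth = M if config.se_method == "newey_west" else None
    else:
        K = T - 1 if config.max_lag == "all" else min(config.max_lag, T - 1)
        acf = sample_acf(x, K)
        fit = fit_nls(acf, config, sampling_interval=x.sampling_interval)
        if config.se_method == "naive":
            se_phi, se_tau = naive_se_acf(acf, fit.phi)
            bandwidth = None
        elif config.se_method == "newey_west":
            M_acf = default_bandwidth(K) if config.bandwidth == "auto" else config.bandwidth
            se_phi, se_tau = nw_se_acf(acf, fit.phi, M_acf)
            bandwidth = M_acf
        else:
            se_phi, se_tau = hybrid_se(x, fit.phi, M)
            bandwidth = M
    return fit.with_se(
        se_phi, se_tau, x.sampling_interval, config.se_method, bandwidth
    )


@dataclass
class SubjectFitMap:
    """One subject's per-vertex timescale fits."""

    subject_id: str
    fits: list[TimescaleFit]
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        if len(self.fits) < 1:
            raise ValueError("need at least one vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.fits)

    def tau_seconds(self) -> np.ndarray:
        return np.array([fit.tau_seconds for fit in self.fits])

    def se_tau_seconds(self) -> np.ndarray:
        return np.array([fit.se_tau_seconds for fit in self.fits])

    def to_frame(self) -> pd.DataFrame:
        """Tabular form, one row per vertex (the fit TSV layout)."""
        return pd.DataFrame(
            {
                "series_id": np.arange(self.n_vertices),
                "phi": [f.phi for f in self.fits],
                "tau_lags": [f.tau_lags for f in self.fits],
                "tau_seconds": [f.tau_seconds for f in self.fits],
                "se_phi": [f.se_phi for f in self.fits],
                "se_tau_seconds": [f.se_tau_seconds for f in self.fits],
                "fit_domain": [f.fit_domain for f in self.fits],
                "se_method": [f.se_method for f in self.fits],
                "bandwidth": [f.bandwidth for f in self.fits],
                "n_lags": [f.n_lags for f in self.fits],
                "converged": [f.converged for f in self.fits],
                "flags": [",".join(sorted(f.flags)) for f in self.fits],
            }
        )


def _degenerate_fit() -> TimescaleFit:
    nan = math.nan
    return TimescaleFit(
        phi=nan,
        tau_lags=nan,
        tau_seconds=nan,
        converged=False,
        flags=frozenset({"degenerate_input"}),
    )


def fit_map(
    X: np.ndarray,
    config: FitConfig = FitConfig(),
    sampling_interval: float = 1.0,
    subject_id: str = "subject",
) -> SubjectFitMap:
    """Fit every column of a timepoints-by-vertices matrix independently.

    Degenerate columns (constant signal) are flagged and carry NaN
    estimates; they never abort the remaining columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-D matrix (timepoints x vertices)")
    fits = []
    for j in range(X.shape[1]):
        x = TimeSeriesSample(
            values=X[:, j], sampling_interval=sampling_interval
        )
        try:
            fits.append(fit_series(x, config))
        except DegenerateInputError:
            fits.append(_degenerate_fit())
    return SubjectFitMap(
        subject_id=subject_id, fits=fits, sampling_interval=sampling_interval
    )


@dataclass
class GroupMap:
    """Vertex-wise group summary of timescale maps (all units: seconds).

    ``se_group`` combines within-subject sampling variance (mean squared
    SE) and between-subject dispersion by the law of total variance; it
    describes the total variability of a single subject's estimate unless
    ``scale_by_n`` was requested at combination time, in which case it is
    the standard error of the group mean.  ``within_var``/``between_var``
    expose the two terms for audit.
    """

    tau_bar: np.ndarray
    se_group: np.ndarray
    n_used: np.ndarray
    n_subjects: int
    within_var: np.ndarray
    between_var: np.ndarray
    scaled_by_n: bool = False
    t_stat: Optional[np.ndarray] = None
    rse: Optional[np.ndarray] = None
    tau_0: Optional[float] = None

    @property
    def n_vertices(self) -> int:
        return self.tau_bar.size

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "vertex_id": np.arange(self.n_vertices),
                "n_used": self.n_used,
                "tau_bar_s": self.tau_bar,
                "se_group_s": self.se_group,
            }
        )
        frame["t_stat"] = self.t_stat if self.t_stat is not None else np.nan
        frame["rse"] = self.rse if self.rse is not None else np.nan
        return frame


def group_combine(
    maps: Sequence[SubjectFitMap], scale_by_n: bool = False
) -> GroupMap:
    """Combine subject maps into a group map (means and combined SEs).

    Per vertex, ``tau_bar`` is the mean timescale across subjects and
    ``se_group = sqrt(mean(se_n**2) + mean((tau_n - tau_bar)**2))`` — the
    law of total variance with the within- and between-subject terms each
    averaged over subjects.  With ``scale_by_n`` the bracketed variance is
    additionally divided by the number of subjects used, giving the SE of
    the mean.  Subjects with non-finite estimates at a vertex are dropped
    there, and the retained count is reported per vertex; vertices with no
    usable subject are NaN.

    All inputs are combined in seconds, so subjects may differ in sampling
    interval.
    """
    if len(maps) < 2:
        raise ValueError("need at least two subject maps")
    V = maps[0].n_vertices
    if any(m.n_vertices != V for m in maps):
        raise ValueError("all subject maps must share the same number of vertices")

    tau = np.vstack([m.tau_seconds() for m in maps])  # (N, V)
    se = np.vstack([m.se_tau_seconds() for m in maps])
    usable = np.isfinite(tau) & np.isfinite(se)
    n_used = usable.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        tau_masked = np.where(usable, tau, np.nan)
        se_masked = np.where(usable, se, np.nan)
        tau_bar = np.nanmean(np.where(usable, tau, np.nan), axis=0)
        within = np.nanmean(se_masked**2, axis=0)
        between = np.nanmean((tau_masked - tau_bar) ** 2, axis=0)
        variance = within + between
        if scale_by_n:
            variance = variance / n_used
        se_group = np.sqrt(variance)
    empty = n_used == 0
    tau_bar[empty] = np.nan
    se_group[empty] = np.nan
    return GroupMap(
        tau_bar=tau_bar,
        se_group=se_group,
        n_used=n_used,
        n_subjects=len(maps),
        within_var=within,
        between_var=between,
        scaled_by_n=scale_by_n,
    )


def group_stats(
    group: GroupMap, tau_0: float = DEFAULT_TAU_THRESHOLD_S
) -> GroupMap:
    """Fill t-statistic and relative-SE maps on a combined group map.

    ``t = (tau_bar - tau_0) / se_group`` tests H0: tau <= tau_0 (default
    threshold 0.5 s) vertex-wise; ``rse = se_group / tau_bar`` maps spatial
    precision.  A vertex with zero SE yields ``t = 0`` if its mean equals
    the threshold exactly and signed infinity otherwise; ``rse`` is NaN
    where the mean timescale is zero.
    """
    tau_bar, se_group = group.tau_bar, group.se_group
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (tau_bar - tau_0) / se_group
        zero_se = se_group == 0
        t = np.where(zero_se & (tau_bar == tau_0), 0.0, t)
        t = np.where(
            zero_se & (tau_bar != tau_0), np.sign(tau_bar - tau_0) * np.inf, t
        )
        rse = np.where(tau_bar != 0, se_group / tau_bar, np.nan)
    return replace(group, t_stat=t, rse=rse, tau_0=tau_0)
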