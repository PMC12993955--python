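"""Estimation of time-varying average allelic effects.

Two estimators are provided for the per-locus average effects alpha_i(t)
from population time-series data.

* Static: at every developmental time t, an independent OLS regression of
  the observed trait on genotype scores with an intercept,

      y(t) = mu(t) 1 + Z alpha(t) + eps(t),  eps ~ N(0, sigma_eps^2 I).

* Dynamic: the average effect follows developmental dynamics and therefore
  carries memory; it is modelled as a random walk

      alpha_i(t) = alpha_i(t-1) + eta(t),  eta ~ N(0, Q),

  and the static estimates are treated as noisy observations with variance
  given by their OLS sampling variance.  A scalar Kalman filter per locus
  assimilates the whole history up to t, which suppresses the sampling
  noise of the per-time regressions.

The benchmark error metric is the relative error against the small-effect
ground truth gamma_i * s(t): |alpha_hat_i(t) - gamma_i s(t)| / |gamma_i s(t)|,
averaged over loci and developmental times (excluding t0, where the
sensitivity — and hence the truth — is exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PhenotypeSeries

__all__ = [
    "StaticEstimate",
    "KalmanConfig",
    "DynamicEstimate",
    "static_average_effects",
    "kalman_average_effects",
    "relative_error",
    "ErrorSummary",
]


@dataclass(frozen=True)
class StaticEstimate:
    """Per-time OLS estimates of average effects."""

    times: np.ndarray  # (T,)
    alpha: np.ndarray  # (T, N) slopes
    se: np.ndarray  # (T, N) OLS standard errors
    mu: np.ndarray  # (T,) intercepts
    sigma2_eps: np.ndarray  # (T,) residual variances

    def to_frame(self):
        import pandas as pd

        T, N = self.alpha.shape
        tt, ll = np.meshgrid(self.times, np.arange(N), indexing="ij")
        return pd.DataFrame(
            {
                "locus": ll.ravel(),
                "time": tt.ravel(),
                "estimate": self.alpha.ravel(),
                "se": self.se.ravel(),
                "method": "static",
            }
        )


@dataclass(frozen=True)
class KalmanConfig:
    """Random-walk filter settings.

    ``q_process``: process-noise variance Q.  ``None`` selects a per-locus
    method-of-moments plug-in: the median squared first difference of the
    static estimates, minus twice the median observation variance (the part
    of the differences explained by sampling noise), floored at a small
    positive fraction of the raw median.  ``r_mode`` chooses the observation
    variance: the OLS sampling variance per time point ("from_ols_se") or a
    fixed value ("fixed", with ``r_value``).
    """

    q_process: float | None = None
    r_mode: str = "from_ols_se"
    r_value: float | None = None
    init_mean: float = 0.0
    init_var: float = 1e-12
    smooth: bool = False

    def __post_init__(self) -> None:
        if self.q_process is not None and self.q_process < 0:
            raise ValueError("q_process must be >= 0")
        if self.r_mode not in ("from_ols_se", "fixed"):
            raise ValueError("r_mode must be 'from_ols_se' or 'fixed'")
        if self.r_mode == "fixed" and (self.r_value is None or self.r_value < 0):
            raise ValueError("fixed r_mode requires a nonnegative r_value")


@dataclass(frozen=True)
class DynamicEstimate:
    """Kalman-filtered average effects."""

    times: np.ndarray
    alpha: np.ndarray  # (T, N) filtered means
    var: np.ndarray  # (T, N) filtered variances

    def to_frame(self):
        import pandas as pd

        T, N = self.alpha.shape
        tt, ll = np.meshgrid(self.times, np.arange(N), indexing="ij")
        return pd.DataFrame(
            {
                "locus": ll.ravel(),
                "time": tt.ravel(),
                "estimate": self.alpha.ravel(),
                "var": self.var.ravel(),
                "method": "dynamic",
            }
        )


def static_average_effects(
    series: PhenotypeSeries, trait_index: int = 0
) -> StaticEstimate:
    """Independent OLS fit of the genotype regression at every time point.

    The design matrix (intercept + genotype scores) is constant over time,
    so its pseudoinverse is factored once and applied to all time points.
    """
    Z = series.genotypes.codes.astype(float)
    M, N = Z.shape
    if M <= N + 1:
        raise ValueError(
            f"need more individuals ({M}) than loci + 1 ({N + 1}) for identifiability"
        )
    X = np.column_stack([np.ones(M), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < N + 1:
        bad = [
            i
            for i in range(N)
            if np.linalg.matrix_rank(np.delete(X, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"genotype matrix is rank deficient; collinear loci: {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T  # (N+1, M)
    Y = series.trait(trait_index)  # (M, T)
    coef = pinv @ Y  # (N+1, T)
    resid = Y - X @ coef
    dof = M - (N + 1)
    sigma2 = np.einsum("mt,mt->t", resid, resid) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)[1:]))  # (T, N)
    return StaticEstimate(
        times=series.times,
        alpha=coef[1:].T,
        se=se,
        mu=coef[0],
        sigma2_eps=sigma2,
    )


def _plugin_q(alpha_s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Method-of-moments process variance per locus.

    E[(d alpha_s)^2] = Q + R_t + R_{t-1}; the observation-noise part is
    removed using medians for robustness, with a positive floor so the
    filter never degenerates to a constant model.
    """
    d2 = np.diff(alpha_s, axis=0) ** 2  # (T-1, N)
    raw = np.median(d2, axis=0)
    q = raw - 2.0 * np.median(r, axis=0)
    return np.maximum(q, 0.01 * raw + 1e-300)


def kalman_average_effects(
    static: StaticEstimate, config: KalmanConfig = KalmanConfig()
) -> DynamicEstimate:
    """Forward Kalman filter over the static estimates, one scalar filter
    per locus.

    The state is alpha_i(t) with random-walk transition; the observation at
    time t is the static OLS estimate with its sampling variance.  The
    filter is initialized at zero with negligible variance because the
    sensitivity — and hence the true average effect — vanishes at t0.
    Setting ``config.smooth`` adds a backward (RTS) pass.
    """
    y = static.alpha  # (T, N)
    T, N = y.shape
    if T < 2:
        raise ValueError("need at least two time points")
    if not np.all(np.isfinite(y)):
        raise ValueError("static estimates contain non-finite values")
    if config.r_mode == "from_ols_se":
        R = static.se**2
    else:
        R = np.full((T, N), float(config.r_value))
    if config.q_process is None:
        Q = _plugin_q(y, R)  # (N,)
    else:
        Q = np.full(N, float(config.q_process))

    m = np.full(N, config.init_mean)
    v = np.full(N, config.init_var)
    mean = np.empty((T, N))
    var = np.empty((T, N))
    m_pred = np.empty((T, N))
    v_pred = np.empty((T, N))
    for t in range(T):
        if t > 0:
            v = v + Q
        m_pred[t], v_pred[t] = m, v
        denom = v + R[t]
        gain = np.where(denom > 0, v / np.where(denom > 0, denom, 1.0), 0.0)
        m = m + gain * (y[t] - m)
        v = (1.0 - gain) * v
        # exact observations (R=0 with informative prior) pin the state
        exact = (R[t] == 0) & (denom == 0)
        m = np.where(exact, y[t], m)
        mean[t], var[t] = m, v

    if config.smooth:
        for t in range(T - 2, -1, -1):
            c = np.where(v_pred[t + 1] > 0, var[t] / v_pred[t + 1], 0.0)
            mean[t] = mean[t] + c * (mean[t + 1] - m_pred[t + 1])
            var[t] = var[t] + c**2 * (var[t + 1] - v_pred[t + 1])
    return DynamicEstimate(times=static.times, alpha=mean, var=var)


@dataclass(frozen=True)
class ErrorSummary:
    """Relative-error summaries of an estimate against the ground truth."""

    per_cell: np.ndarray  # (T_used, N) relative errors
    per_time: np.ndarray  # mean over loci
    per_locus: np.ndarray  # mean over times
    mean: float


def relative_error(
    estimate: np.ndarray, truth: np.ndarray, skip_initial: int = 1
) -> ErrorSummary:
    """|estimate - truth| / |truth| averaged over loci and times.

    The first ``skip_initial`` time points are excluded: the truth is zero
    at t0 (zero initial sensitivity), where relative error is undefined.
    """
    estimate = np.asarray(estimate, float)
    truth = np.asarray(truth, float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth shapes differ")
    est = estimate[skip_initial:]
    tru = truth[skip_initial:]
    if np.all(tru == 0):
        raise ValueError("truth is identically zero; relative error undefined")
    err = np.abs(est - tru) / np.abs(tru)
    return ErrorSummary(
        per_cell=err,
        per_time=err.mean(axis=1),
        per_locus=err.mean(axis=0),
        mean=float(err.mean()),
    )
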