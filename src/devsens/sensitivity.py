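"""Sensitivity vectors of developmental trajectories.

The sensitivity vector of parameter k,

    s_k(t) = d x(t, lam) / d lam_k  evaluated at the reference lam*,

measures how every phenotypic variable responds to an infinitesimal change
of one developmental parameter.  It obeys the variational (forward
sensitivity) equation

    ds_k/dt = A(t) s_k + b_k(t),   s_k(t0) = 0,

with A the Jacobian of the vector field along the reference trajectory and
b_k its direct parameter derivative.  Three routes are provided: joint
integration of the variational system (exact up to solver tolerance),
central finite differences of trajectories (derivative-free), and
regression on perturbed simulations (for black-box simulators).  Angle
statistics between sensitivity vectors, and the null distribution of
angles between random directions, support alignment analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    ODESystem,
    TimeGrid,
    Trajectory,
    integrate,
)

__all__ = [
    "SensitivitySet",
    "SecondOrderSet",
    "AngleReport",
    "sensitivities_variational",
    "sensitivities_fd",
    "second_order_fd",
    "sensitivities_regression",
    "angle",
    "pairwise_angles",
    "random_angle_null",
    "angle_pdf",
    "angle_cdf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivitySet:
    """Time-indexed first-order sensitivities: ``s[t, :, k]`` is s_k(t)."""

    times: np.ndarray  # (T,)
    s: np.ndarray  # (T, n, p)
    method: str
    lam_ref: np.ndarray
    trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.s)):
            raise ValueError("sensitivities contain non-finite values")
        if self.s.shape[0] != self.times.shape[0]:
            raise ValueError("times and s length mismatch")

    @property
    def n_params(self) -> int:
        return self.s.shape[2]

    @property
    def n_states(self) -> int:
        return self.s.shape[1]

    def at_time(self, t: float) -> np.ndarray:
        """The (n, p) sensitivity matrix at grid time t."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise KeyError(f"time {t} not on the sensitivity grid")
        return self.s[idx]

    def to_frame(self):
        """Tidy table (time, state_index, param_index, value)."""
        import pandas as pd

        T, n, p = self.s.shape
        tt, ss, pp = np.meshgrid(self.times, np.arange(n), np.arange(p), indexing="ij")
        return pd.DataFrame(
            {
                "time": tt.ravel(),
                "state_index": ss.ravel(),
                "param_index": pp.ravel(),
                "value": self.s.ravel(),
            }
        )


@dataclass(frozen=True)
class SecondOrderSet:
    """Second derivatives of the trajectory w.r.t. each parameter."""

    times: np.ndarray
    s1: np.ndarray  # (T, n, p)


@dataclass(frozen=True)
class AngleReport:
    """Pairwise angles between parameter sensitivity vectors over time."""

    times: np.ndarray
    pairs: list[tuple[int, int]]
    angle_by_time: np.ndarray  # (T, n_pairs), degrees
    convention: str

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, (k, l) in enumerate(self.pairs):
            for i, t in enumerate(self.times):
                rows.append((t, k, l, self.angle_by_time[i, j]))
        return pd.DataFrame(rows, columns=["time", "param_k", "param_l", "angle_deg"])


# ---------------------------------------------------------------------------
# First-order sensitivities
# ---------------------------------------------------------------------------


def sensitivities_variational(
    system: ODESystem,
    x0: Sequence[float],
    lam_ref: Sequence[float],
    grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SensitivitySet:
    """Integrate the augmented (state + all sensitivities) system jointly.

    The augmented state is [x, vec(S)] with S the n x p sensitivity matrix;
    dS/dt = A(t, x) S + B(t, x) is evaluated on the trajectory being
    integrated, so reference trajectory and sensitivities stay consistent.
    """
    lam_ref = np.asarray(lam_ref, dtype=float)
    n, p = system.n_states, system.n_params

    def aug_rhs(t, y, _lam):
        x = y[:n]
        S = y[n:].reshape(n, p)
        A = system.jacobian_x(t, x, lam_ref)
        B = system.jacobian_lambda(t, x, lam_ref)
        return np.concatenate([system.rhs(t, x, lam_ref), (A @ S + B).ravel()])

    aug = ODESystem(
        n_states=n + n * p,
        n_params=lam_ref.size,
        rhs=aug_rhs,
        name=f"{system.name}_variational",
    )
    y0 = np.concatenate([np.asarray(x0, dtype=float), np.zeros(n * p)])
    traj = integrate(aug, y0, lam_ref, grid, rtol=rtol, atol=atol)
    states = traj.states[:, :n]
    s = traj.states[:, n:].reshape(-1, n, p)
    return SensitivitySet(
        times=traj.times,
        s=s,
        method="variational",
        lam_ref=lam_ref,
        trajectory=Trajectory(times=traj.times, states=states),
    )


def sensitivities_fd(
    system: ODESystem,
    x0: Sequence[float],
    lam_ref: Sequence[float],
    grid: TimeGrid,
    dlam: float = 1e-4,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SensitivitySet:
    """Central-difference sensitivities (x(lam*+d e_k) - x(lam*-d e_k)) / 2d."""
    if dlam <= 0:
        raise ValueError("dlam must be positive")
    lam_ref = np.asarray(lam_ref, dtype=float)
    n, p = system.n_states, system.n_params
    ref = integrate(system, x0, lam_ref, grid, rtol=rtol, atol=atol)
    s = np.empty((grid.times.size, n, p))
    for k in range(p):
        dk = np.zeros(p)
        dk[k] = dlam
        plus = integrate(system, x0, lam_ref + dk, grid, rtol=rtol, atol=atol)
        minus = integrate(system, x0, lam_ref - dk, grid, rtol=rtol, atol=atol)
        diff = plus.states - minus.states
        if np.max(np.abs(diff)) < 10 * atol:
            warnings.warn(
                f"finite-difference step dlam={dlam} produces differences near "
                "solver tolerance; sensitivities may be dominated by noise",
                stacklevel=2,
            )
        s[:, :, k] = diff / (2 * dlam)
    return SensitivitySet(
        times=grid.times, s=s, method="finite_difference", lam_ref=lam_ref, trajectory=ref
    )


def second_order_fd(
    system: ODESystem,
    x0: Sequence[float],
    lam_ref: Sequence[float],
    grid: TimeGrid,
    dlam: float = 1e-3,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SecondOrderSet:
    """Second parameter derivatives by the central second difference.

    The second difference divides by dlam**2, amplifying solver error by
    ~1/dlam**2; tolerances therefore default tighter than elsewhere.
    """
    if dlam <= 0:
        raise ValueError("dlam must be positive")
    lam_ref = np.asarray(lam_ref, dtype=float)
    n, p = system.n_states, system.n_params
    ref = integrate(system, x0, lam_ref, grid, rtol=rtol, atol=atol)
    s1 = np.empty((grid.times.size, n, p))
    for k in range(p):
        dk = np.zeros(p)
        dk[k] = dlam
        plus = integrate(system, x0, lam_ref + dk, grid, rtol=rtol, atol=atol)
        minus = integrate(system, x0, lam_ref - dk, grid, rtol=rtol, atol=atol)
        s1[:, :, k] = (plus.states - 2 * ref.states + minus.states) / dlam**2
    return SecondOrderSet(times=grid.times, s1=s1)


def sensitivities_regression(
    trajectories: Sequence[Trajectory] | np.ndarray,
    param_draws: np.ndarray,
    lam_ref: Sequence[float],
    times: np.ndarray | None = None,
) -> SensitivitySet:
    """Estimate sensitivities by regressing phenotypes on parameter offsets.

    For each time and trait, the phenotype across runs is regressed (OLS,
    with intercept) on the parameter deviations lam - lam*; the slope matrix
    is the sensitivity estimate.  Only simulator output is needed, so this
    route applies to black-box models with no accessible vector field.

    Parameters
    ----------
    trajectories : list of Trajectory, or array (R, T, n)
    param_draws : array (R, p), the parameter vector of each run
    """
    lam_ref = np.asarray(lam_ref, dtype=float)
    param_draws = np.asarray(param_draws, dtype=float)
    if isinstance(trajectories, np.ndarray):
        Y = trajectories
        if times is None:
            raise ValueError("times required when passing a raw array")
    else:
        times = trajectories[0].times
        Y = np.stack([tr.states for tr in trajectories])  # (R, T, n)
    R, T, n = Y.shape
    p = param_draws.shape[1]
    if R < p + 2:
        raise ValueError(f"need at least p+2={p + 2} runs, got {R}")
    X = np.column_stack([np.ones(R), param_draws - lam_ref])
    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        # identify which parameter columns are linearly dependent
        bad = [
            k
            for k in range(p)
            if np.linalg.matrix_rank(np.delete(X, k + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear parameter indices: {bad}")
    coef, *_ = np.linalg.lstsq(X, Y.reshape(R, T * n), rcond=None)
    s = coef[1:].T.reshape(T, n, p)
    return SensitivitySet(
        times=np.asarray(times, float), s=s, method="regression", lam_ref=lam_ref
    )


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------


def angle(u: np.ndarray, v: np.ndarray, convention: str = "directed") -> float:
    """Angle between two vectors, in degrees.

    ``directed`` returns values in [0, 180]; ``axial`` folds sign-ambiguous
    directions (e.g. eigenvectors) into [0, 90] by taking |cos|.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angle undefined for zero vectors")
    uh, vh = u / nu, v / nv
    c = float(np.dot(uh, vh))
    # atan2 of the orthogonal component keeps full precision for nearly
    # (anti)parallel vectors, where arccos saturates
    s = float(np.linalg.norm(vh - c * uh))
    if convention == "axial":
        c = abs(c)
    elif convention != "directed":
        raise ValueError("convention must be 'directed' or 'axial'")
    return float(np.degrees(np.arctan2(s, c)))


def pairwise_angles(
    sens: SensitivitySet,
    pairs: Sequence[tuple[int, int]] | None = None,
    convention: str = "directed",
    skip_t0: bool = True,
) -> AngleReport:
    """Angles between sensitivity vectors of parameter pairs over time.

    t0 is skipped by default: all sensitivities start at the zero vector,
    where the angle is undefined.
    """
    p = sens.n_params
    if pairs is None:
        pairs = [(k, l) for k in range(p) for l in range(k + 1, p)]
    start = 1 if skip_t0 else 0
    times = sens.times[start:]
    out = np.empty((times.size, len(pairs)))
    for i, ti in enumerate(range(start, sens.times.size)):
        for j, (k, l) in enumerate(pairs):
            out[i, j] = angle(sens.s[ti, :, k], sens.s[ti, :, l], convention)
    return AngleReport(times=times, pairs=list(pairs), angle_by_time=out, convention=convention)


def random_angle_null(dim: int, n_samples: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample angles between pairs of independent isotropic directions.

    In dimension d the angle between two uniformly random directions has
    density proportional to sin(theta)^(d-2) on [0, 180] degrees; this is
    the null against which alignment of sensitivity vectors is judged.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.standard_normal((n_samples, dim))
    v = rng.standard_normal((n_samples, dim))
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def angle_pdf(theta_deg: np.ndarray, dim: int) -> np.ndarray:
    """Closed-form density of random angles (per degree) in a given dimension."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    norm = np.sqrt(np.pi) * special.gamma((dim - 1) / 2) / special.gamma(dim / 2)
    return np.sin(theta) ** (dim - 2) / norm * (np.pi / 180.0)


def angle_cdf(theta_deg: np.ndarray, dim: int) -> np.ndarray:
    """Closed-form CDF of random angles via the regularized incomplete beta."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    theta = np.clip(theta, 0.0, np.pi)
    half = 0.5 * special.betainc((dim - 1) / 2, 0.5, np.sin(theta) ** 2)
    return np.where(theta <= np.pi / 2, half, 1.0 - half)
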