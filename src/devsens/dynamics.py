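"""Developmental dynamical systems and their numerical integration.

Development is represented as an initial-value problem

    dx/dt = f(t, x, lam),   x(t0) = x0,

where the state vector ``x`` collects the phenotypic variables (gene
expression levels, trait measurements, ...) and ``lam`` is a vector of
developmental parameters of genetic or environmental origin (regulatory
strengths, degradation rates, ...).  The module provides a generic
:class:`ODESystem` container, the built-in two-gene toggle switch used
throughout the package, trajectory integration on a fixed output grid, and
equilibrium finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "IntegrationError",
    "ODESystem",
    "TimeGrid",
    "Trajectory",
    "ToggleSwitchParams",
    "toggle_switch",
    "get_model",
    "MODEL_REGISTRY",
    "integrate",
    "integrate_batch",
    "find_equilibria",
    "is_stable",
]

# Defaults chosen tight because sensitivities amplify solver error.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
_FD_STEP = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the solver fails or produces non-finite states."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform output grid {t0, t0+h, ..., t_end}.

    The default unit step (h=1) matches the discrete steps used by the
    time-series estimators; the integrator takes adaptive internal steps
    regardless of h.
    """

    t0: float = 0.0
    t_end: float = 50.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("step size h must be positive")
        if self.t_end < self.t0:
            raise ValueError("t_end must be >= t0")
        n_steps = (self.t_end - self.t0) / self.h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("grid length (t_end - t0) must be a multiple of h")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t0) / self.h))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class Trajectory:
    """Solution sampled on a grid: ``states[t]`` is x(times[t])."""

    times: np.ndarray
    states: np.ndarray  # (T, n)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states length mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, individual_id: int = 0):
        """Tidy long-format table (individual_id, time, state_index, value)."""
        import pandas as pd

        T, n = self.states.shape
        return pd.DataFrame(
            {
                "individual_id": individual_id,
                "time": np.repeat(self.times, n),
                "state_index": np.tile(np.arange(n), T),
                "value": self.states.ravel(),
            }
        )


@dataclass
class ODESystem:
    """A developmental dynamical system f(t, x, lam).

    ``jac_x`` (the n x n Jacobian A = df/dx) and ``jac_lambda`` (the
    n x p matrix whose k-th column b_k = df/dlam_k) may be analytic; when
    absent they are approximated by central finite differences of ``rhs``.
    ``rhs_batch``, if provided, evaluates the vector field for a whole
    population at once: (t, X (M,n), Lam (M,p)) -> (M,n).
    """

    n_states: int
    n_params: int
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    jac_x: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | None = None
    jac_lambda: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | None = None
    rhs_batch: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = "ode_system"

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_params < 1:
            raise ValueError("n_states and n_params must be positive")

    def jacobian_x(self, t: float, x: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """A(t) = df/dx, analytic when available, else central differences."""
        if self.jac_x is not None:
            return np.asarray(self.jac_x(t, x, lam), dtype=float)
        return _fd_jacobian(lambda xx: self.rhs(t, xx, lam), np.asarray(x, float))

    def jacobian_lambda(self, t: float, x: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """Columns b_k = df/dlam_k, analytic when available."""
        if self.jac_lambda is not None:
            return np.asarray(self.jac_lambda(t, x, lam), dtype=float)
        return _fd_jacobian(lambda ll: self.rhs(t, x, ll), np.asarray(lam, float))

    def batch_rhs(self, t: float, X: np.ndarray, Lam: np.ndarray) -> np.ndarray:
        if self.rhs_batch is not None:
            return np.asarray(self.rhs_batch(t, X, Lam), dtype=float)
        return np.stack([self.rhs(t, X[m], Lam[m]) for m in range(X.shape[0])])


def _fd_jacobian(fun: Callable[[np.ndarray], np.ndarray], z: np.ndarray) -> np.ndarray:
    f0 = np.asarray(fun(z), dtype=float)
    jac = np.empty((f0.size, z.size))
    for k in range(z.size):
        step = _FD_STEP * max(1.0, abs(z[k]))
        zp, zm = z.copy(), z.copy()
        zp[k] += step
        zm[k] -= step
        jac[:, k] = (np.asarray(fun(zp), float) - np.asarray(fun(zm), float)) / (2 * step)
    return jac


# ---------------------------------------------------------------------------
# Built-in model: two-gene toggle switch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToggleSwitchParams:
    """Structural constants of the mutually repressive two-gene switch."""

    basal: float = 2.0
    decay: float = 0.4
    hill_on_x2: int = 2  # exponent of x2 repressing gene 1
    hill_on_x1: int = 3  # exponent of x1 repressing gene 2
    outer_power: int = 2  # the whole denominator is squared

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("decay must be positive")


def toggle_switch(
    params: ToggleSwitchParams | None = None, include_env: bool = False
) -> ODESystem:
    """Two-gene mutually repressive switch, bistable at reference parameters.

        dx1/dt = (basal + lam1) / (1 + x2^2)^2      - decay * x1
        dx2/dt = (basal + lam2) / (1 + x1^3 + lam3)^2 - decay * x2

    ``lam1`` and ``lam2`` modulate the regulatory input each gene receives
    (genetically determined in the package's population scenarios).  With
    ``include_env=True`` a third, environmentally determined parameter
    ``lam3`` shifts the repression term of gene 2: x1^3 is replaced by
    (x1^3 + lam3) inside the squared denominator.  This is the single place
    where the algebraic form of the switch is defined.
    """
    p = params or ToggleSwitchParams()
    n_params = 3 if include_env else 2
    basal, decay = p.basal, p.decay
    e2, e1, pw = p.hill_on_x2, p.hill_on_x1, p.outer_power

    def _den(x1, x2, lam3):
        # den1 represses gene 1 (via x2), den2 represses gene 2 (via x1 + env)
        den1 = (1.0 + x2**e2) ** pw
        inner = 1.0 + x1**e1 + lam3
        den2 = inner**pw
        return den1, den2, inner

    def _core(x1, x2, lam1, lam2, lam3):
        den1, den2, _ = _den(x1, x2, lam3)
        d1 = (basal + lam1) / den1 - decay * x1
        d2 = (basal + lam2) / den2 - decay * x2
        return d1, d2

    def rhs(t, x, lam):
        # delegate to the batch path so scalar and population integrations
        # use bit-identical arithmetic (scalar ** and array ** differ in the
        # last ulp on some platforms)
        x = np.asarray(x, dtype=float)
        lam = np.asarray(lam, dtype=float)
        return rhs_batch(t, x[None, :], lam[None, :])[0]

    def rhs_batch(t, X, Lam):
        lam3 = Lam[:, 2] if include_env else 0.0
        d1, d2 = _core(X[:, 0], X[:, 1], Lam[:, 0], Lam[:, 1], lam3)
        return np.stack([d1, d2], axis=1)

    def jac_x(t, x, lam):
        x1, x2 = x[0], x[1]
        lam3 = lam[2] if include_env else 0.0
        den1_inner = 1.0 + x2**e2
        inner = 1.0 + x1**e1 + lam3
        # d/dx2 of (basal+lam1)*(1+x2^e2)^-pw
        d12 = -(basal + lam[0]) * pw * e2 * x2 ** (e2 - 1) * den1_inner ** (-pw - 1)
        d21 = -(basal + lam[1]) * pw * e1 * x1 ** (e1 - 1) * inner ** (-pw - 1)
        return np.array([[-decay, d12], [d21, -decay]])

    def jac_lambda(t, x, lam):
        x1, x2 = x[0], x[1]
        lam3 = lam[2] if include_env else 0.0
        den1, den2, inner = _den(x1, x2, lam3)
        cols = np.zeros((2, n_params))
        cols[0, 0] = 1.0 / den1
        cols[1, 1] = 1.0 / den2
        if include_env:
            cols[1, 2] = -(basal + lam[1]) * pw * inner ** (-pw - 1)
        return cols

    return ODESystem(
        n_states=2,
        n_params=n_params,
        rhs=rhs,
        jac_x=jac_x,
        jac_lambda=jac_lambda,
        rhs_batch=rhs_batch,
        name="toggle_switch_env" if include_env else "toggle_switch",
    )


MODEL_REGISTRY: dict[str, Callable[[], ODESystem]] = {
    "toggle_switch": lambda: toggle_switch(include_env=False),
    "toggle_switch_env": lambda: toggle_switch(include_env=True),
}


def get_model(name: str) -> ODESystem:
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _step_segment(fun, t0: float, t1: float, y0: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    sol = solve_ivp(fun, (t0, t1), y0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"integration failed in segment starting at t={t0}: {sol.message}")
    y = sol.y[:, -1]
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t1}")
    return y


def integrate(
    system: ODESystem,
    x0: Sequence[float],
    lam: Sequence[float],
    grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Deterministic solution of the system sampled exactly on the grid.

    Integration proceeds segment by segment between consecutive grid points
    (the adaptive solver restarts at every output time).  This makes the
    result of an uninterrupted run identical to a run that is paused and
    resumed at grid points, which is what the stochastic population
    simulator does when it injects developmental noise between steps.
    """
    x0 = np.asarray(x0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x0.shape != (system.n_states,):
        raise ValueError(f"x0 must have length {system.n_states}")
    if lam.shape != (system.n_params,):
        raise ValueError(f"lam must have length {system.n_params}")
    times = grid.times
    states = np.empty((times.size, system.n_states))
    states[0] = x0
    fun = lambda t, y: system.rhs(t, y, lam)
    for k in range(times.size - 1):
        states[k + 1] = _step_segment(fun, times[k], times[k + 1], states[k], rtol, atol)
    return Trajectory(times=times, states=states)


def integrate_batch(
    system: ODESystem,
    X0: np.ndarray,
    Lam: np.ndarray,
    grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    perturb: Callable[[int, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Integrate a whole population jointly; returns (M, T, n) states.

    All individuals are stacked into one vector field and advanced with a
    single adaptive solver, which is orders of magnitude faster than a
    Python loop over individuals.  ``perturb(step_index, X) -> X`` is an
    optional hook applied to the (M, n) state block after each grid step
    (used for developmental noise); the returned array is recorded and used
    as the initial condition of the next segment.
    """
    X0 = np.asarray(X0, dtype=float)
    Lam = np.asarray(Lam, dtype=float)
    M, n = X0.shape
    if Lam.shape != (M, system.n_params):
        raise ValueError("Lam must be (M, n_params)")
    times = grid.times
    out = np.empty((M, times.size, n))
    X = X0.copy()
    if perturb is not None:
        X = perturb(0, X)
    out[:, 0, :] = X

    for k in range(times.size - 1):
        # individuals with identical (state, parameters) obey identical
        # ODEs: integrate each distinct row once and scatter the result
        # back.  This also makes a clone population bit-identical to the
        # single-trajectory integrator.
        uniq, inverse = np.unique(
            np.hstack([X, Lam]), axis=0, return_inverse=True
        )
        Xu, Lu = uniq[:, :n], uniq[:, n:]
        mu = Xu.shape[0]

        def fun(t, y):
            return system.batch_rhs(t, y.reshape(mu, n), Lu).ravel()

        try:
            y = _step_segment(fun, times[k], times[k + 1], Xu.ravel(), rtol, atol)
        except IntegrationError as err:
            raise IntegrationError(f"population integration failed: {err}") from err
        X = y.reshape(mu, n)[inverse]
        if perturb is not None:
            X = perturb(k + 1, X)
        out[:, k + 1, :] = X
    return out


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------


def find_equilibria(
    system: ODESystem,
    lam: Sequence[float],
    starts: Sequence[Sequence[float]],
    residual_tol: float = 1e-8,
    dedup_tol: float = 1e-6,
) -> list[np.ndarray]:
    """Roots of f(., x, lam) = 0 from each start, deduplicated.

    Starts that do not converge are silently dropped; an empty list is a
    valid result.
    """
    if len(starts) == 0:
        raise ValueError("starts must be nonempty")
    lam = np.asarray(lam, dtype=float)
    found: list[np.ndarray] = []
    for s in starts:
        sol = root(
            lambda x: system.rhs(0.0, x, lam),
            np.asarray(s, dtype=float),
            jac=lambda x: system.jacobian_x(0.0, x, lam),
        )
        if not sol.success:
            continue
        res = np.linalg.norm(system.rhs(0.0, sol.x, lam))
        if res >= residual_tol:
            continue
        if all(np.linalg.norm(sol.x - e) > dedup_tol for e in found):
            found.append(sol.x)
    return found


def is_stable(system: ODESystem, x_eq: np.ndarray, lam: Sequence[float]) -> bool:
    """Linear (eigenvalue) stability of an equilibrium."""
    eigs = np.linalg.eigvals(system.jacobian_x(0.0, np.asarray(x_eq, float), np.asarray(lam, float)))
    return bool(np.all(eigs.real < 0))
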