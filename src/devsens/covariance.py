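"""Additive-genetic, environmental and phenotypic covariance matrices.

Under the small-effect approximation the average effects of locus i are
proportional to the sensitivity vector of its target parameter, so the
locus contributes the rank-1 additive-genetic term

    G_i(t) = 2 p_i q_i gamma_i^2  s_{w(i)}(t) s_{w(i)}(t)^T,

with sigma_i^2 = 2 p_i q_i gamma_i^2 the variance the locus generates in
its developmental parameter.  Environmental factors contribute analogously,
E_j(t) = sigma_j^2 s_{v(j)}(t) s_{v(j)}(t)^T, and to first order the
phenotypic matrix is P(t) = G(t) + E(t).

Proportionality between G and P therefore depends jointly on the geometry
of the sensitivity vectors (a property of development) and on how much
variance the aligned parameters carry in the population.  The leading-axis
angle between Gmax and Pmax is the diagnostic reported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetics import Locus
from .population import EnvFactor, PhenotypeSeries
from .sensitivity import SensitivitySet, angle

__all__ = [
    "CovarianceSet",
    "ProportionalityReport",
    "build_G",
    "build_E",
    "build_P",
    "build_covariances",
    "empirical_G",
    "leading_eigenvector",
    "gmax_pmax_angle",
]


@dataclass(frozen=True)
class CovarianceSet:
    """G, E and P at one developmental time, with per-source contributions."""

    time: float
    G: np.ndarray  # (n, n)
    E: np.ndarray  # (n, n)
    per_locus: list[np.ndarray] = field(default_factory=list)
    per_env: list[np.ndarray] = field(default_factory=list)
    sigma2_by_locus: np.ndarray | None = None
    sigma2_by_env: np.ndarray | None = None

    @property
    def P(self) -> np.ndarray:
        return self.G + self.E


@dataclass(frozen=True)
class ProportionalityReport:
    """Leading-axis alignment between G and P."""

    time: float
    angle_gmax_pmax: float  # degrees, axial convention
    gmax: np.ndarray
    pmax: np.ndarray
    g_eigenvalues: np.ndarray
    p_eigenvalues: np.ndarray


def _sens_at(sens: SensitivitySet, t: float, param: int) -> np.ndarray:
    S = sens.at_time(t)
    if param >= S.shape[1]:
        raise ValueError(
            f"no sensitivity available for parameter {param} "
            f"(set has {S.shape[1]} parameters)"
        )
    return S[:, param]


def build_G(
    sens: SensitivitySet, loci: Sequence[Locus], t: float
) -> CovarianceSet:
    """Additive genetic covariance at time t as a sum of rank-1 locus terms."""
    n = sens.n_states
    per_locus = []
    sigma2 = np.empty(len(loci))
    G = np.zeros((n, n))
    for i, locus in enumerate(loci):
        q = locus.freq_B
        sigma2[i] = 2.0 * (1.0 - q) * q * locus.gamma**2
        s = _sens_at(sens, t, locus.target_param)
        Gi = sigma2[i] * np.outer(s, s)
        per_locus.append(Gi)
        G += Gi
    return CovarianceSet(
        time=t, G=G, E=np.zeros((n, n)), per_locus=per_locus,
        sigma2_by_locus=sigma2,
    )


def build_E(
    sens: SensitivitySet, env_factors: Sequence[EnvFactor], t: float
) -> np.ndarray:
    """First-order environmental covariance at time t."""
    n = sens.n_states
    E = np.zeros((n, n))
    for f in env_factors:
        s = _sens_at(sens, t, f.target_param)
        E += f.sd**2 * np.outer(s, s)
    return E


def build_P(G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Phenotypic covariance to first order: the elementwise sum G + E."""
    G = np.asarray(G, float)
    E = np.asarray(E, float)
    if G.shape != E.shape:
        raise ValueError("G and E dimensions differ")
    return G + E


def build_covariances(
    sens: SensitivitySet,
    loci: Sequence[Locus],
    env_factors: Sequence[EnvFactor],
    t: float,
) -> CovarianceSet:
    """Assemble the full G/E/P set at time t from one sensitivity set."""
    gset = build_G(sens, loci, t)
    per_env = []
    sigma2_env = np.empty(len(env_factors))
    n = sens.n_states
    E = np.zeros((n, n))
    for j, f in enumerate(env_factors):
        s = _sens_at(sens, t, f.target_param)
        sigma2_env[j] = f.sd**2
        Ej = sigma2_env[j] * np.outer(s, s)
        per_env.append(Ej)
        E += Ej
    return CovarianceSet(
        time=t,
        G=gset.G,
        E=E,
        per_locus=gset.per_locus,
        per_env=per_env,
        sigma2_by_locus=gset.sigma2_by_locus,
        sigma2_by_env=sigma2_env,
    )


def empirical_G(
    series: PhenotypeSeries,
    alpha: np.ndarray,
    t_index: int = -1,
) -> np.ndarray:
    """Additive covariance from realized allele frequencies.

    ``alpha`` is the (T, n_traits, N) array of per-locus average-effect
    vectors (e.g. from :func:`devsens.genetics.average_effect_linear`); the
    estimate is 2 sum_i p_hat_i q_hat_i alpha_i alpha_i^T with frequencies
    realized in the sample, evaluated at time index ``t_index``.
    """
    q_hat = series.genotypes.realized_freq_B()
    A = alpha[t_index]  # (n, N)
    w = 2.0 * q_hat * (1.0 - q_hat)  # (N,)
    return (A * w) @ A.T


def leading_eigenvector(M: np.ndarray, tie_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpair of a symmetric matrix with a deterministic sign.

    Raises if the top two eigenvalues tie within ``tie_tol`` (relative),
    since the leading axis is then undefined.  The sign is fixed by making
    the largest-magnitude component positive.
    """
    M = np.asarray(M, float)
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    evals, evecs = np.linalg.eigh(M)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    if evals[0] <= 0:
        raise ValueError("matrix has no positive leading eigenvalue")
    if M.shape[0] > 1 and (evals[0] - evals[1]) <= tie_tol * abs(evals[0]):
        raise ValueError("leading eigenvalue is (numerically) degenerate")
    v = evecs[:, 0]
    k = int(np.argmax(np.abs(v)))
    if v[k] < 0:
        v = -v
    return v, evals


def gmax_pmax_angle(cov: CovarianceSet) -> ProportionalityReport:
    """Axial angle between the leading eigenvectors of G and P.

    Scale-free: multiplying G or P by any positive constant leaves the
    angle unchanged, matching the norm-normalized comparison convention.
    """
    gmax, g_evals = leading_eigenvector(cov.G)
    pmax, p_evals = leading_eigenvector(cov.P)
    return ProportionalityReport(
        time=cov.time,
        angle_gmax_pmax=angle(gmax, pmax, convention="axial"),
        gmax=gmax,
        pmax=pmax,
        g_eigenvalues=g_evals,
        p_eigenvalues=p_evals,
    )
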