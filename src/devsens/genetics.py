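"""Genetic architecture: loci, genotypes, and average allelic effects.

The genotype-to-phenotype map is decomposed into two steps: an additive map
from genotype scores to developmental parameters, and the (generally
nonlinear) developmental map from parameters to phenotypic trajectories.
Each biallelic locus i targets one developmental parameter w(i) and shifts
it by gamma_i per B allele; the heterozygote-at-all-loci maps to the
reference parameter vector lam*.  Nonlinearity of development is what
generates dominance at the trait level even though the parameter map is
purely additive.

Genotypes are coded as (count of B alleles - 1): +1 for BB, 0 for Bb,
-1 for bb.  With gamma = lam_BB - lam_Bb this makes the regression of
phenotype on genotype score return the average effect alpha(t) with the
sign convention alpha ~ s(t) * gamma for small effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import ODESystem, TimeGrid, Trajectory, integrate
from .sensitivity import SensitivitySet

__all__ = [
    "Locus",
    "GenotypeMatrix",
    "EffectCurves",
    "genotype_to_parameters",
    "genotypic_values",
    "effect_curves",
    "average_effect_linear",
    "sample_genotypes",
]


@dataclass(frozen=True)
class Locus:
    """A biallelic locus acting additively on one developmental parameter.

    Attributes
    ----------
    target_param : int
        0-based index of the developmental parameter the locus affects.
    gamma : float
        Per-allele substitution effect on that parameter (lam_BB - lam_Bb).
    freq_B : float
        Frequency q of allele B (p = 1 - q is the frequency of b).
    """

    target_param: int
    gamma: float
    freq_B: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_B <= 1.0:
            raise ValueError("freq_B must lie in [0, 1]")
        if self.target_param < 0:
            raise ValueError("target_param must be a valid 0-based index")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Genotype scores for M individuals at N loci.

    ``codes`` holds (count of B alleles - 1) in {-1, 0, +1}.  ``alleles``
    optionally stores the two allele copies per individual and locus
    (0 = b, 1 = B), shape (M, N, 2); it is required for Mendelian
    segregation in the selection module and kept consistent with codes.
    """

    codes: np.ndarray  # (M, N) int
    alleles: np.ndarray | None = None  # (M, N, 2) int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        object.__setattr__(self, "codes", codes)
        if not np.isin(codes, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be -1, 0 or +1")
        if self.alleles is not None:
            alleles = np.asarray(self.alleles)
            object.__setattr__(self, "alleles", alleles)
            if alleles.shape != codes.shape + (2,):
                raise ValueError("alleles must have shape (M, N, 2)")
            if not np.array_equal(alleles.sum(axis=2) - 1, codes):
                raise ValueError("alleles inconsistent with codes")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def realized_freq_B(self) -> np.ndarray:
        """Realized B-allele frequency per locus."""
        return (self.codes.mean(axis=0) + 1.0) / 2.0


@dataclass(frozen=True)
class EffectCurves:
    """Additive a(t), dominance d(t) and average effect alpha(t) per trait.

    a(t) is half the difference between homozygote trajectories, d(t) the
    deviation of the heterozygote from the homozygote midpoint, and under
    random mating (Hardy-Weinberg genotype frequencies) the regression of
    phenotype on the genotype score (B-allele count - 1) has slope

        alpha(t) = a(t) + d(t) (p - q),

    with q the frequency of B and p = 1 - q.  At q = 0.5 the dominance term
    drops and alpha(t) = a(t) exactly.
    """

    times: np.ndarray
    a: np.ndarray  # (T, n)
    d: np.ndarray  # (T, n)
    alpha: np.ndarray  # (T, n)


def genotype_to_parameters(
    genotypes: GenotypeMatrix,
    loci: Sequence[Locus],
    lam_ref: Sequence[float],
) -> np.ndarray:
    """Additive genotype -> developmental-parameter map; returns (M, p).

    lam(individual) = lam* + sum_i code_i * gamma_i * e_{w(i)}; an
    all-heterozygote individual maps exactly to lam*.
    """
    lam_ref = np.asarray(lam_ref, dtype=float)
    if genotypes.n_loci != len(loci):
        raise ValueError("number of loci does not match genotype columns")
    W = np.zeros((len(loci), lam_ref.size))
    for i, locus in enumerate(loci):
        if locus.target_param >= lam_ref.size:
            raise ValueError(f"locus {i} targets parameter {locus.target_param} "
                             f"but lam has length {lam_ref.size}")
        W[i, locus.target_param] = locus.gamma
    return lam_ref + genotypes.codes @ W


def genotypic_values(
    system: ODESystem,
    x0: Sequence[float],
    grid: TimeGrid,
    locus: Locus,
    lam_ref: Sequence[float],
    **integrate_kwargs,
) -> tuple[Trajectory, Trajectory, Trajectory]:
    """Deterministic trajectories of the three genotypes at one locus.

    Returns (x_bb, x_Bb, x_BB): the heterozygote develops at lam*, the
    homozygotes at lam* -/+ gamma on the locus's target parameter.
    """
    lam_ref = np.asarray(lam_ref, dtype=float)
    shift = np.zeros_like(lam_ref)
    shift[locus.target_param] = locus.gamma
    x_bb = integrate(system, x0, lam_ref - shift, grid, **integrate_kwargs)
    x_Bb = integrate(system, x0, lam_ref, grid, **integrate_kwargs)
    x_BB = integrate(system, x0, lam_ref + shift, grid, **integrate_kwargs)
    return x_bb, x_Bb, x_BB


def effect_curves(
    x_bb: Trajectory, x_Bb: Trajectory, x_BB: Trajectory, freq_B: float
) -> EffectCurves:
    """Classical single-locus decomposition at every developmental time.

    The dominance weight (p - q) is the one that makes ``alpha`` coincide
    exactly with the slope of the frequency-weighted regression of
    phenotype on the genotype score under Hardy-Weinberg proportions (q is
    the frequency of the allele whose substitution effect is +gamma).
    """
    if not (np.array_equal(x_bb.times, x_Bb.times) and np.array_equal(x_Bb.times, x_BB.times)):
        raise ValueError("genotypic-value trajectories must share the time grid")
    a = (x_BB.states - x_bb.states) / 2.0
    d = x_Bb.states - (x_BB.states + x_bb.states) / 2.0
    q = freq_B
    p = 1.0 - q
    alpha = a + d * (p - q)
    return EffectCurves(times=x_bb.times, a=a, d=d, alpha=alpha)


def average_effect_linear(sens: SensitivitySet, loci: Sequence[Locus]) -> np.ndarray:
    """Small-effect approximation alpha_i(t) = gamma_i * s_{w(i)}(t).

    Returns an array (T, n_traits, N_loci).  This is the infinitesimal-model
    limit of the average effect and serves as the analytic ground truth when
    scoring estimators.
    """
    T, n, _ = sens.s.shape
    out = np.empty((T, n, len(loci)))
    for i, locus in enumerate(loci):
        out[:, :, i] = locus.gamma * sens.s[:, :, locus.target_param]
    return out


def sample_genotypes(
    loci: Sequence[Locus],
    n_individuals: int,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Draw unlinked Hardy-Weinberg genotypes; allele copies are retained."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.array([locus.freq_B for locus in loci])
    alleles = (rng.random((n_individuals, len(loci), 2)) < q[None, :, None]).astype(np.int64)
    codes = alleles.sum(axis=2) - 1
    return GenotypeMatrix(codes=codes, alleles=alleles)
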