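"""Synthetic populations of developmental trajectories.

This is the package's data engine: it maps sampled genotypes (plus
environmental draws) to developmental parameters, develops every individual
through the ODE model, and corrupts the trajectories with two kinds of
noise.

* Developmental noise: independent Gaussian perturbations added to each
  state variable at every unit time step during development, with standard
  deviation proportional to the current absolute state value.  The
  perturbed state is the initial condition of the next step, so the noise
  propagates through the remaining dynamics.
* Measurement noise: Gaussian noise added to the recorded values only,
  again with SD proportional to the absolute state value.

Scenario factories reproduce the package's three study designs: a
single-locus teaching population, the estimator benchmark (replicated
populations with 10 loci per genetic parameter), and the alignment /
selection design (large population, variable minor allele frequency on the
second parameter, environmentally perturbed third parameter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import genetics
from .dynamics import ODESystem, TimeGrid, integrate_batch, toggle_switch
from .genetics import GenotypeMatrix, Locus
from .sensitivity import SensitivitySet, sensitivities_variational

__all__ = [
    "NoiseConfig",
    "EnvFactor",
    "PhenotypeSeries",
    "ScenarioBundle",
    "simulate_population",
    "scenario_single_locus",
    "scenario_estimation",
    "scenario_alignment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseConfig:
    """Relative noise magnitudes (fractions of the current trait value)."""

    dev_sd_rel: float = 0.0
    meas_sd_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.dev_sd_rel < 0 or self.meas_sd_rel < 0:
            raise ValueError("noise fractions must be >= 0")


@dataclass(frozen=True)
class EnvFactor:
    """An environmental variable perturbing one developmental parameter.

    Each individual receives an independent Gaussian draw N(0, sd) added to
    parameter ``target_param``; sigma2 = sd**2 is the parameter variance
    used when building the environmental covariance matrix.
    """

    target_param: int
    sd: float


@dataclass(frozen=True)
class PhenotypeSeries:
    """Observed and latent developmental time series for a population."""

    times: np.ndarray  # (T,)
    observed: np.ndarray  # (M, T, n)
    true_states: np.ndarray  # (M, T, n), pre-measurement-noise
    genotypes: GenotypeMatrix
    env_params: np.ndarray  # (M, n_env)
    lam: np.ndarray  # (M, p) realized developmental parameters

    @property
    def n_individuals(self) -> int:
        return self.observed.shape[0]

    @property
    def n_traits(self) -> int:
        return self.observed.shape[2]

    def trait(self, trait_index: int) -> np.ndarray:
        """Observed values of one trait, shape (M, T)."""
        return self.observed[:, :, trait_index]

    def final_phenotypes(self) -> np.ndarray:
        """Observed state vectors at the last developmental time, (M, n)."""
        return self.observed[:, -1, :]

    def to_frame(self):
        """Tidy table (individual, time, trait, observed, true)."""
        import pandas as pd

        M, T, n = self.observed.shape
        idx, tt, kk = np.meshgrid(np.arange(M), self.times, np.arange(n), indexing="ij")
        return pd.DataFrame(
            {
                "individual": idx.ravel(),
                "time": tt.ravel(),
                "trait": kk.ravel(),
                "observed": self.observed.ravel(),
                "true": self.true_states.ravel(),
            }
        )


def simulate_population(
    system: ODESystem,
    x0: Sequence[float],
    grid: TimeGrid,
    genotypes: GenotypeMatrix,
    loci: Sequence[Locus],
    lam_ref: Sequence[float],
    env_factors: Sequence[EnvFactor] = (),
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
) -> PhenotypeSeries:
    """Develop a population and observe it with noise.

    All individuals are integrated jointly (stacked vector field); with all
    noise off and an all-heterozygote population this reproduces the
    deterministic reference trajectory exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    M = genotypes.n_individuals
    lam = genetics.genotype_to_parameters(genotypes, loci, lam_ref)
    env = np.zeros((M, len(env_factors)))
    for j, f in enumerate(env_factors):
        env[:, j] = rng.normal(0.0, f.sd, size=M)
        lam[:, f.target_param] += env[:, j]

    if noise.dev_sd_rel > 0:

        def perturb(step: int, X: np.ndarray) -> np.ndarray:
            if step == 0:
                return X
            return X + rng.normal(0.0, 1.0, size=X.shape) * noise.dev_sd_rel * np.abs(X)

    else:
        perturb = None

    X0 = np.broadcast_to(x0, (M, x0.size)).copy()
    true_states = integrate_batch(system, X0, lam, grid, perturb=perturb)
    if np.any(true_states < -1):
        logger.info("developmental noise drove %d state values below -1",
                    int(np.sum(true_states < -1)))
    if noise.meas_sd_rel > 0:
        observed = true_states + rng.normal(0.0, 1.0, size=true_states.shape) * (
            noise.meas_sd_rel * np.abs(true_states)
        )
    else:
        observed = true_states.copy()
    return PhenotypeSeries(
        times=grid.times,
        observed=observed,
        true_states=true_states,
        genotypes=genotypes,
        env_params=env,
        lam=lam,
    )


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything a downstream analysis needs about one simulated scenario."""

    system: ODESystem
    x0: np.ndarray
    grid: TimeGrid
    lam_ref: np.ndarray
    loci: list[Locus]
    env_factors: list[EnvFactor]
    series: PhenotypeSeries
    sens: SensitivitySet
    alpha_true: np.ndarray  # (T, n_traits, N_loci), small-effect ground truth


def _bundle(system, x0, grid, lam_ref, loci, env_factors, series, sens=None):
    if sens is None:
        sens = sensitivities_variational(system, x0, lam_ref, grid)
    alpha_true = genetics.average_effect_linear(sens, loci)
    return ScenarioBundle(
        system=system,
        x0=np.asarray(x0, float),
        grid=grid,
        lam_ref=np.asarray(lam_ref, float),
        loci=list(loci),
        env_factors=list(env_factors),
        series=series,
        sens=sens,
        alpha_true=alpha_true,
    )


def exact_hw_genotypes(n_individuals: int, n_loci: int = 1) -> GenotypeMatrix:
    """Deterministic genotypes at exact Hardy-Weinberg proportions, q=0.5.

    n_individuals must be a multiple of 4 so the counts (M/4 bb, M/2 Bb,
    M/4 BB) are integers; the per-locus columns are identical.
    """
    if n_individuals % 4:
        raise ValueError("n_individuals must be a multiple of 4")
    quarter = n_individuals // 4
    col = np.concatenate(
        [-np.ones(quarter), np.zeros(2 * quarter), np.ones(quarter)]
    ).astype(np.int64)
    codes = np.tile(col[:, None], (1, n_loci))
    alleles = np.stack([(codes >= 0).astype(np.int64), (codes > 0).astype(np.int64)], axis=2)
    return GenotypeMatrix(codes=codes, alleles=alleles)


def scenario_single_locus(
    gamma: float = 1e-2,
    n_individuals: int = 20,
    t_end: float = 50.0,
    seed: int = 0,
) -> ScenarioBundle:
    """A noise-free population with one biallelic locus on lam1 (q = 0.5).

    Genotype counts are fixed at exact Hardy-Weinberg proportions so the
    regression estimate of the average effect is deterministic.  The default
    matches the package's teaching example: 20 individuals, gamma = 0.01,
    trait of interest = gene-1 expression.
    """
    system = toggle_switch()
    x0 = np.zeros(2)
    grid = TimeGrid(0.0, t_end, 1.0)
    lam_ref = np.zeros(2)
    loci = [Locus(target_param=0, gamma=gamma, freq_B=0.5)]
    genotypes = exact_hw_genotypes(n_individuals, 1)
    series = simulate_population(
        system, x0, grid, genotypes, loci, lam_ref, noise=NoiseConfig(), seed=seed
    )
    return _bundle(system, x0, grid, lam_ref, loci, [], series)


def scenario_estimation(
    n_individuals: int,
    dev_sd_rel: float,
    meas_sd_rel: float,
    n_replicates: int,
    seed: int = 0,
    n_loci_per_param: int = 10,
    gamma_sd: float = 0.01,
    t_end: float = 50.0,
    sens: SensitivitySet | None = None,
) -> list[ScenarioBundle]:
    """Replicated populations for benchmarking average-effect estimators.

    Each genetic parameter (lam1, lam2) is determined by ``n_loci_per_param``
    loci at frequency 0.5 whose effects are drawn fresh per replicate from
    N(0, gamma_sd**2); developmental and measurement noise are applied at
    the requested relative magnitudes.
    """
    system = toggle_switch()
    x0 = np.zeros(2)
    grid = TimeGrid(0.0, t_end, 1.0)
    lam_ref = np.zeros(2)
    rng = np.random.default_rng(seed)
    if sens is None:
        sens = sensitivities_variational(system, x0, lam_ref, grid)
    bundles = []
    for _ in range(n_replicates):
        gammas = rng.normal(0.0, gamma_sd, size=2 * n_loci_per_param)
        loci = [
            Locus(target_param=k, gamma=gammas[k * n_loci_per_param + i], freq_B=0.5)
            for k in range(2)
            for i in range(n_loci_per_param)
        ]
        genotypes = genetics.sample_genotypes(loci, n_individuals, rng)
        series = simulate_population(
            system,
            x0,
            grid,
            genotypes,
            loci,
            lam_ref,
            noise=NoiseConfig(dev_sd_rel=dev_sd_rel, meas_sd_rel=meas_sd_rel),
            seed=rng,
        )
        bundles.append(_bundle(system, x0, grid, lam_ref, loci, [], series, sens=sens))
    return bundles


def scenario_alignment(
    maf_lam2: float,
    n_individuals: int = 5000,
    seed: int = 0,
    n_loci_per_param: int = 10,
    gamma_sd: float = 1e-4,
    env_sd: float = 1.5e-3,
    t_end: float = 50.0,
    sens: SensitivitySet | None = None,
) -> ScenarioBundle:
    """Alignment / selection design on the environmentally extended switch.

    lam1 loci segregate at frequency 0.5; lam2 loci at the requested minor
    allele frequency; per-locus effects are N(0, gamma_sd**2); lam3 is an
    environmental factor drawn per individual from N(0, env_sd**2).
    Phenotypes are the two gene-expression levels at developmental time
    ``t_end`` (default 50), with no developmental or measurement noise.
    """
    system = toggle_switch(include_env=True)
    x0 = np.zeros(2)
    grid = TimeGrid(0.0, t_end, 1.0)
    lam_ref = np.zeros(3)
    rng = np.random.default_rng(seed)
    gammas = rng.normal(0.0, gamma_sd, size=2 * n_loci_per_param)
    freqs = [0.5, maf_lam2]
    loci = [
        Locus(target_param=k, gamma=gammas[k * n_loci_per_param + i], freq_B=freqs[k])
        for k in range(2)
        for i in range(n_loci_per_param)
    ]
    env_factors = [EnvFactor(target_param=2, sd=env_sd)]
    genotypes = genetics.sample_genotypes(loci, n_individuals, rng)
    series = simulate_population(
        system, x0, grid, genotypes, loci, lam_ref,
        env_factors=env_factors, noise=NoiseConfig(), seed=rng,
    )
    return _bundle(system, x0, grid, lam_ref, loci, env_factors, series, sens=sens)
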