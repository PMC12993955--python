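"""One generation of truncation selection, breeding, and response prediction.

The selection design: develop a parental population, keep the fraction of
individuals whose final-time phenotype is closest (Euclidean) to an
optimum, pair the survivors randomly and monogamously, and produce a fixed
number of offspring per pair by Mendelian segregation at unlinked loci.
Offspring develop through the same ODE model with fresh environmental
draws.

The realized response (offspring mean minus pre-selection parental mean) is
compared with the multivariate breeder's equation

    delta_z = G beta,   beta = P^-1 S,

where S is the selection differential.  Substituting P for G — the common
proxy when G is unavailable — predicts P P^-1 S = S, so the quality of the
proxy is judged by the angle each prediction makes with the observed
response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import ODESystem, TimeGrid
from .genetics import GenotypeMatrix, Locus
from .population import EnvFactor, NoiseConfig, PhenotypeSeries, simulate_population
from .sensitivity import angle

__all__ = [
    "SelectionConfig",
    "ResponseReport",
    "select_and_breed",
    "breeders_prediction",
    "response_report",
    "run_selection_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Truncation selection toward a phenotypic optimum."""

    optimum: tuple[float, ...] = (4.0, 4.0)
    fraction_selected: float = 0.5
    offspring_per_pair: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.fraction_selected <= 1:
            raise ValueError("fraction_selected must be in (0, 1]")
        if self.offspring_per_pair < 1:
            raise ValueError("offspring_per_pair must be >= 1")


@dataclass(frozen=True)
class ResponseReport:
    """Observed vs predicted one-generation change in trait means."""

    parental_mean: np.ndarray  # pre-selection
    selected_mean: np.ndarray
    offspring_mean: np.ndarray
    S: np.ndarray  # selection differential
    observed_dz: np.ndarray
    predicted_dz_G: np.ndarray
    predicted_dz_P: np.ndarray
    angle_G_obs: float | None  # degrees, axial
    angle_P_obs: float | None


def _mendelian_offspring(
    parents: GenotypeMatrix,
    mothers: np.ndarray,
    fathers: np.ndarray,
    offspring_per_pair: int,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Segregate one allele per parent per locus, independently across loci."""
    if parents.alleles is None:
        raise ValueError("parent genotypes must carry allele pairs for segregation")
    n_pairs = mothers.size
    N = parents.n_loci
    n_off = n_pairs * offspring_per_pair
    mom = np.repeat(parents.alleles[mothers], offspring_per_pair, axis=0)  # (n_off, N, 2)
    dad = np.repeat(parents.alleles[fathers], offspring_per_pair, axis=0)
    pick_m = rng.integers(0, 2, size=(n_off, N))
    pick_d = rng.integers(0, 2, size=(n_off, N))
    a1 = np.take_along_axis(mom, pick_m[:, :, None], axis=2)[:, :, 0]
    a2 = np.take_along_axis(dad, pick_d[:, :, None], axis=2)[:, :, 0]
    alleles = np.stack([a1, a2], axis=2)
    return GenotypeMatrix(codes=alleles.sum(axis=2) - 1, alleles=alleles)


def select_and_breed(
    series: PhenotypeSeries,
    loci: Sequence[Locus],
    lam_ref: Sequence[float],
    system: ODESystem,
    x0: Sequence[float],
    grid: TimeGrid,
    config: SelectionConfig = SelectionConfig(),
    env_factors: Sequence[EnvFactor] = (),
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[PhenotypeSeries, np.ndarray]:
    """Select parents, breed, and develop the offspring generation.

    Returns the offspring :class:`PhenotypeSeries` and the indices of the
    selected parents.  Selection ranks individuals by Euclidean distance of
    the final-time phenotype to the optimum; ties are broken by index.  The
    number selected is rounded down to an even count so every selected
    parent mates exactly once.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phen = series.final_phenotypes()
    M = phen.shape[0]
    optimum = np.asarray(config.optimum, dtype=float)
    dist = np.linalg.norm(phen - optimum, axis=1)
    n_sel = int(np.floor(M * config.fraction_selected))
    if n_sel % 2:
        n_sel -= 1
        logger.info("selected count rounded down to even: %d", n_sel)
    if n_sel < 2:
        raise ValueError("fewer than 2 individuals selected")
    selected = np.argsort(dist, kind="stable")[:n_sel]
    order = rng.permutation(n_sel)
    mothers = selected[order[: n_sel // 2]]
    fathers = selected[order[n_sel // 2:]]
    offspring = _mendelian_offspring(
        series.genotypes, mothers, fathers, config.offspring_per_pair, rng
    )
    off_series = simulate_population(
        system, x0, grid, offspring, loci, lam_ref,
        env_factors=env_factors, noise=noise, seed=rng,
    )
    return off_series, selected


def breeders_prediction(
    S: np.ndarray, G: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate breeder's-equation predictions.

    beta = P^-1 S is the selection gradient; the prediction with the true
    additive matrix is G beta, while using P as its own proxy gives
    P P^-1 S = S exactly.
    """
    S = np.asarray(S, float)
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    try:
        beta = np.linalg.solve(P, S)
    except np.linalg.LinAlgError as err:
        raise ValueError("P matrix is singular; selection gradient undefined") from err
    return G @ beta, S.copy()


def response_report(
    parental: PhenotypeSeries,
    offspring: PhenotypeSeries,
    selected: np.ndarray,
    G: np.ndarray,
    P: np.ndarray,
) -> ResponseReport:
    """Assemble means, differentials, predictions and alignment angles.

    Angles are axial (in [0, 90]); they are ``None`` when the selection
    differential vanishes (no selection), where direction is undefined.
    """
    par = parental.final_phenotypes()
    parental_mean = par.mean(axis=0)
    selected_mean = par[selected].mean(axis=0)
    offspring_mean = offspring.final_phenotypes().mean(axis=0)
    S = selected_mean - parental_mean
    observed = offspring_mean - parental_mean
    pred_G, pred_P = breeders_prediction(S, G, P)
    scale = 1.0 + np.linalg.norm(parental_mean)
    if np.linalg.norm(S) < 1e-12 * scale or np.linalg.norm(observed) < 1e-12 * scale:
        ang_G = ang_P = None
    else:
        ang_G = angle(pred_G, observed, convention="axial")
        ang_P = angle(pred_P, observed, convention="axial")
    return ResponseReport(
        parental_mean=parental_mean,
        selected_mean=selected_mean,
        offspring_mean=offspring_mean,
        S=S,
        observed_dz=observed,
        predicted_dz_G=pred_G,
        predicted_dz_P=pred_P,
        angle_G_obs=ang_G,
        angle_P_obs=ang_P,
    )


def run_selection_experiment(bundle, config: SelectionConfig = SelectionConfig(),
                             seed: int | np.random.Generator = 0) -> ResponseReport:
    """Full one-generation experiment on an alignment-scenario bundle.

    Uses the analytic G (from the known architecture and sensitivities at
    the final time) and the empirical phenotypic covariance of the full
    parental generation as P, then selects, breeds, and reports response
    alignment.
    """
    from .covariance import build_G

    t_end = bundle.grid.t_end
    G = build_G(bundle.sens, bundle.loci, t_end).G
    P_emp = np.cov(bundle.series.final_phenotypes(), rowvar=False)
    offspring, selected = select_and_breed(
        bundle.series, bundle.loci, bundle.lam_ref, bundle.system, bundle.x0,
        bundle.grid, config=config, env_factors=bundle.env_factors, seed=seed,
    )
    return response_report(bundle.series, offspring, selected, G, P_emp)
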