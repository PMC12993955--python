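"""Headline experiment drivers.

Each driver assembles a full pipeline run — scenario simulation, estimation
or covariance construction, and summary statistics — and returns a plain
dict of numbers.  Defaults are scaled down (smaller populations, fewer
replicates) so a full sweep completes in minutes on one CPU; the
``full_scale`` flag switches to the full study sizes.  The summaries are
flagged with the scale actually used.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import covariance as vc
from . import dynamics as dyn
from . import estimators as est
from . import population as pop
from . import selection as sel
from . import sensitivity as sens

__all__ = ["run_experiment"]


def _toggle_sens(include_env: bool, t_end: float = 50.0) -> sens.SensitivitySet:
    system = dyn.toggle_switch(include_env=include_env)
    return sens.sensitivities_variational(
        system, np.zeros(2), np.zeros(system.n_params), dyn.TimeGrid(0.0, t_end, 1.0)
    )


def single_locus(seed: int = 0, full_scale: bool = False) -> dict:
    """Convergence of the regression average effect to gamma * s(t).

    A noise-free 20-individual population with one locus on lam1 at exact
    Hardy-Weinberg proportions (q = 0.5).  Reports the maximum relative
    deviation of the per-time regression slope from the sensitivity
    prediction over t in [5, 50], for gamma = 0.01 and gamma = 0.005 (the
    deviation is a second-order Taylor remainder, so halving gamma should
    shrink it about fourfold).
    """
    out: dict = {"scaled_down": False}
    for label, gamma in (("gamma_0.01", 1e-2), ("gamma_0.005", 5e-3)):
        bundle = pop.scenario_single_locus(gamma=gamma, seed=seed)
        static = est.static_average_effects(bundle.series, trait_index=0)
        truth = bundle.alpha_true[:, 0, 0]
        i0 = int(np.searchsorted(bundle.grid.times, 5.0))
        rel = np.abs(static.alpha[i0:, 0] - truth[i0:]) / np.abs(truth[i0:])
        out[label] = {"max_rel_dev": float(rel.max()), "n_individuals": 20}
    out["shrink_factor"] = out["gamma_0.01"]["max_rel_dev"] / out["gamma_0.005"]["max_rel_dev"]
    return out


def estimator_benchmark(
    seed: int = 0,
    full_scale: bool = False,
    n_replicates: int = 100,
    pop_sizes: tuple[int, ...] | None = None,
) -> dict:
    """Static vs Kalman average-effect error across the noise grid.

    Grid: population size x measurement noise {1%, 8%} x developmental
    noise {1%, 20%}, with 10 loci per genetic parameter and per-replicate
    effects gamma ~ N(0, 0.01^2).  Errors are relative to the sensitivity
    ground truth gamma_i s(t) on the gene-1 trait, averaged over loci and
    t >= 1.  Population sizes default to {64, 512} (scaled down); the full
    scale uses {64, 256, 1024, 4096}.
    """
    if pop_sizes is None:
        pop_sizes = (64, 256, 1024, 4096) if full_scale else (64, 512)
    sset = _toggle_sens(include_env=False)
    rng = np.random.default_rng(seed)
    cells = {}
    for M in pop_sizes:
        for meas in (0.01, 0.08):
            for dev in (0.01, 0.20):
                bundles = pop.scenario_estimation(
                    M, dev, meas, n_replicates,
                    seed=int(rng.integers(2**31)), sens=sset,
                )
                e_static, e_dynamic = [], []
                for b in bundles:
                    static = est.static_average_effects(b.series, trait_index=0)
                    dynamic = est.kalman_average_effects(static)
                    truth = b.alpha_true[:, 0, :]
                    e_static.append(est.relative_error(static.alpha, truth).mean)
                    e_dynamic.append(est.relative_error(dynamic.alpha, truth).mean)
                e_static = np.asarray(e_static)
                e_dynamic = np.asarray(e_dynamic)
                wins = int((e_dynamic < e_static).sum())
                cells[f"M{M}_meas{int(meas * 100)}_dev{int(dev * 100)}"] = {
                    "static_mean_rel_error": float(e_static.mean()),
                    "dynamic_mean_rel_error": float(e_dynamic.mean()),
                    "dynamic_wins": wins,
                    "n_replicates": n_replicates,
                    "sign_test_p": float(
                        stats.binomtest(wins, n_replicates, alternative="greater").pvalue
                    ),
                }
    return {"scaled_down": not full_scale, "cells": cells}


def sensitivity_angles(seed: int = 0, full_scale: bool = False) -> dict:
    """Pairwise angles between the three parameter sensitivity vectors.

    On the environmentally extended switch, the lam2 (genetic) and lam3
    (environmental) sensitivity vectors stay collinear throughout
    development (their direct forcing terms act on the same gene), while
    the lam1 vector decorrelates as the switch resolves.
    """
    sset = _toggle_sens(include_env=True)
    report = sens.pairwise_angles(sset, convention="axial")
    out = {"scaled_down": False, "convention": "axial", "angles_by_time": {}}
    for t in (5.0, 25.0, 50.0):
        i = int(np.argmin(np.abs(report.times - t)))
        out["angles_by_time"][f"t{int(t)}"] = {
            f"lam{k + 1}_lam{l + 1}": float(report.angle_by_time[i, j])
            for j, (k, l) in enumerate(report.pairs)
        }
    return out


def gp_proportionality(
    seed: int = 0, full_scale: bool = False, n_seeds: int = 10
) -> dict:
    """G-P leading-axis angle vs minor allele frequency of the lam2 loci.

    G is assembled from the known architecture (rank-1 locus terms), E from
    the environmental factor, P = G + E, all at developmental time 50;
    randomness across seeds is the per-locus effect draws.  More standing
    variation in the lam2 loci aligns Gmax with the environmentally
    dominated Pmax.
    """
    sset = _toggle_sens(include_env=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_seeds)
    out = {"scaled_down": not full_scale, "angles_deg": {}}
    for maf in (0.001, 0.016, 0.5):
        angles = []
        for s in seeds:
            bundle_rng = np.random.default_rng(int(s))
            gammas = bundle_rng.normal(0.0, 1e-4, 20)
            from .genetics import Locus

            loci = [Locus(0, gammas[i], 0.5) for i in range(10)] + [
                Locus(1, gammas[10 + i], maf) for i in range(10)
            ]
            cov = vc.build_covariances(
                sset, loci, [pop.EnvFactor(target_param=2, sd=1.5e-3)], 50.0
            )
            angles.append(vc.gmax_pmax_angle(cov).angle_gmax_pmax)
        out["angles_deg"][f"maf_{maf}"] = {
            "median": float(np.median(angles)),
            "n_seeds": n_seeds,
        }
    return out


def selection_response(
    seed: int = 0,
    full_scale: bool = False,
    n_seeds: int = 20,
    mafs: tuple[float, ...] = (0.001, 0.5),
) -> dict:
    """Breeder's-equation predictions vs the realized one-generation change.

    For each minor allele frequency, repeat the full experiment over seeds:
    simulate the parental population, truncation-select toward (4, 4),
    breed, and measure the axial angle between the observed mean change and
    (i) the G-based prediction G P^-1 S and (ii) the P-proxy prediction S.
    Default 2,000 individuals per population (full scale: 5,000).
    """
    M = 5000 if full_scale else 2000
    sset = _toggle_sens(include_env=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_seeds)
    out = {"scaled_down": not full_scale, "n_individuals": M, "by_maf": {}}
    for maf in mafs:
        ang_G, ang_P = [], []
        for s in seeds:
            bundle = pop.scenario_alignment(maf, n_individuals=M, seed=int(s), sens=sset)
            report = sel.run_selection_experiment(
                bundle, sel.SelectionConfig(), seed=int(s) + 1
            )
            ang_G.append(report.angle_G_obs)
            ang_P.append(report.angle_P_obs)
        ang_G = np.asarray(ang_G)
        ang_P = np.asarray(ang_P)
        g_wins = int((ang_G < ang_P).sum())
        out["by_maf"][f"maf_{maf}"] = {
            "median_angle_G_obs_deg": float(np.median(ang_G)),
            "median_angle_P_obs_deg": float(np.median(ang_P)),
            "G_wins": g_wins,
            "n_seeds": n_seeds,
            "sign_test_p_two_sided": float(
                stats.binomtest(g_wins, n_seeds).pvalue
            ),
        }
    return out


def angle_null(seed: int = 0, full_scale: bool = False, n_samples: int = 100_000) -> dict:
    """Random-angle null distribution checks in trait-space dimensions 2, 4."""
    out = {"scaled_down": False, "n_samples": n_samples}
    for dim in (2, 4):
        draws = sens.random_angle_null(dim, n_samples, seed=seed)
        ks = stats.kstest(draws, lambda x: sens.angle_cdf(x, dim))
        out[f"dim{dim}"] = {
            "mean_deg": float(draws.mean()),
            "ks_distance": float(ks.statistic),
        }
    return out


_EXPERIMENTS = {
    "single-locus": single_locus,
    "estimator-benchmark": estimator_benchmark,
    "sensitivity-angles": sensitivity_angles,
    "gp-proportionality": gp_proportionality,
    "selection-response": selection_response,
    "angle-null": angle_null,
}


def run_experiment(name: str, seed: int = 0, full_scale: bool = False, **kwargs) -> dict:
    try:
        fn = _EXPERIMENTS[name]
    except KeyError:
        raise KeyError(f"unknown experiment {name!r}; available: {sorted(_EXPERIMENTS)}") from None
    return fn(seed=seed, full_scale=full_scale, **kwargs)
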