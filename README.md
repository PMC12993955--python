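# devsens

Sensitivity analysis of developmental dynamical systems for quantitative
genetics.

## The problem

Quantitative genetics describes phenotypic variation statistically — average
allelic effects α, additive genetic covariance **G**, phenotypic covariance
**P**, and selection responses Δz̄ = **G**β — while treating development as a
black box. `devsens` makes the link between the two levels explicit for any
development that can be written as a dynamical system

    dx/dt = f(t, x, λ),    x(t0) = x0,

where the state **x** collects phenotypic variables (e.g. gene expression
levels) and **λ** is a vector of developmental parameters of genetic or
environmental origin. The key object is the sensitivity vector of parameter
k,

    s_k(t) = ∂x(t, λ)/∂λ_k  at λ = λ*,

which solves the variational equation ṡ_k = A(t) s_k + b_k(t) with
s_k(t0) = 0, A = ∂f/∂x and b_k = ∂f/∂λ_k along the reference trajectory.

With an additive map from genotype scores to developmental parameters
(locus i shifts parameter w(i) by ±γᵢ), a Taylor expansion around the
heterozygote reference gives, at every developmental time t:

* additive value   a(t) = (x_BB − x_bb)/2 = s(t)γ + O(γ³)
* dominance value  d(t) = x_Bb − (x_BB + x_bb)/2 = −s⁽¹⁾(t)γ²/2 − …
* average effect   α(t) ≈ s(t)γ for small γ — the regression-slope
  definition of α and the mechanistic sensitivity coincide.

Consequences implemented here:

* **Estimation.** α(t) follows developmental dynamics, so its time series
  carries memory. Per-time OLS estimates (the static estimator) are
  combined by a random-walk Kalman filter into a dynamic estimator with
  systematically lower error, especially for small samples and high noise.
* **Covariance structure.** Under Hardy–Weinberg equilibrium each locus
  contributes a rank-1 term Gᵢ(t) = 2pᵢqᵢγᵢ² s_{w(i)} s_{w(i)}ᵀ, each
  environmental factor Eⱼ(t) = σⱼ² s_{v(j)} s_{v(j)}ᵀ, and
  P(t) = G(t) + E(t) to first order. Proportionality between G and P
  requires both aligned sensitivity vectors (a property of development)
  and enough variance in the aligned parameters (a property of the
  population).
* **Prediction.** One generation of truncation selection with Mendelian
  breeding is simulated and compared against the multivariate breeder's
  equation Δz̄ = **G**β, β = **P**⁻¹**S**, with **P** as a proxy for **G**
  as the baseline.

The built-in developmental model is a two-gene toggle switch (mutual
repression, bistable):

    dx1/dt = (2 + λ1)/(1 + x2²)² − 0.4 x1
    dx2/dt = (2 + λ2)/(1 + x1³ + λ3)² − 0.4 x2

with λ1, λ2 genetic and λ3 an optional environmental shift of gene-2
regulation. Any user model can be plugged in as an `ODESystem` (a right-hand
side plus optional analytic Jacobians); sensitivities can also be estimated
by regression from black-box simulator output alone.

## Worked example

Estimate the time-resolved average effect of a single biallelic locus from a
noise-free population of 20 individuals and compare it with the sensitivity
prediction γ·s(t):

```python
import numpy as np
from devsens import population as pop, estimators as est

bundle = pop.scenario_single_locus(gamma=0.01)      # 20 ind., q = 0.5, locus on lam1
static = est.static_average_effects(bundle.series, trait_index=0)
truth = bundle.alpha_true[:, 0, 0]                  # gamma * s(t), gene-1 trait
for t in (1, 5, 15, 50):
    print(f"t={t:2d}  alpha_static={static.alpha[t,0]: .6f}  gamma*s={truth[t]: .6f}")
rel = np.abs(static.alpha[5:, 0] - truth[5:]) / np.abs(truth[5:])
print("max relative deviation over t in [5,50]:", f"{rel.max():.4%}")
```

prints

```
t= 1  alpha_static= 0.006005  gamma*s= 0.006005
t= 5  alpha_static= 0.007473  gamma*s= 0.007464
t=15  alpha_static= 0.000212  gamma*s= 0.000212
t=50  alpha_static= 0.000037  gamma*s= 0.000037
max relative deviation over t in [5,50]: 0.1372%
```

The regression slope (a purely statistical, population-level estimate) and
γ·s(t) (integrated from the developmental equations) agree to a fraction of
a percent; the residual gap is the second-order Taylor remainder and shrinks
fourfold when γ is halved. The average effect itself is strongly
time-dependent: it peaks while the switch is still deciding and collapses
once gene 1 is repressed.

The same pipelines are exposed on the command line (`devsens simulate`,
`sensitivities`, `estimate`, `varcomp`, `evolve`, `reproduce`), driven by
YAML/JSON configs with explicit seeds; identical configs reproduce all
artifacts byte for byte.

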