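# qbimc — quasi-Bayesian bilinear regression and inductive matrix completion

`qbimc` estimates the coefficient matrix of the bilinear (growth-curve /
GMANOVA) model

```
Y = X M* Z + E
```

where `Y` (n×q) collects q responses for n individuals, `X` (n×p) is the
between-individuals design, `Z` (k×q) the within-individuals design, and
`M*` (p×k) is unknown and assumed (approximately) low rank. The package
also handles the **inductive matrix completion** setting, in which only a
random subset of the entries of `Y` is observed — the situation of
drug–target or gene–disease association screens, where `X` and `Z` carry
side information about rows and columns.

It is aimed at statisticians and computational biologists who want a
low-rank-aware estimator with missing responses, plus the simulation
machinery to study its behaviour.

## Method

Instead of a likelihood, the posterior is built from a tempered empirical
risk (a *Gibbs* or *quasi-posterior*):

```
rho_lambda(dM) ∝ exp(-lambda * r(M)) pi(dM)
```

with `r(M) = ||Y - Pi_C(XMZ)||_F^2 / (nq)` for a full response, or the mean
squared error over the m observed entries in the completion setting.
`Pi_C` clamps predictions to a known bound C (by default C = ∞, which is
how the simulation studies run), and `lambda > 0` is the inverse
temperature (`lambda = nq/(2σ²)` recovers the Gaussian-likelihood
posterior). The prior is the **spectral scaled Student** distribution

```
pi(M) ∝ det(tau² I + M Mᵀ)^(-(p+k+2)/2) = Π_j (tau² + s_j(M)²)^(-(p+k+2)/2)
```

whose heavy tails on the singular values `s_j(M)` push most of them toward
zero — soft low-rankness without fixing the rank.

Sampling uses Langevin dynamics: the unadjusted chain (LMC)
`M ← M + h ∇log rho(M) + sqrt(2h) N` or its Metropolis-adjusted variant
(MALA), with the step size adapted during burn-in toward a 0.5 acceptance
rate. Comparators are generalized OLS, `(XᵀX)⁺ Xᵀ Y Zᵀ (ZZᵀ)⁺`, and — with
missing entries — OLS on a rank-r hard-impute completion of `Y`. The
`theory` module computes the tuning constants (C1, C2, τ*, λ*) and the
PAC-Bayes oracle-bound radius for a given instance.

## Worked example

Approximately low-rank truth (Model II of the simulation designs) with 30%
of the response entries removed at random:

```python
import numpy as np
from qbimc import BilinearModel, ScenarioSpec, make_dataset, pred_error, nmse

# Model II: approximately rank-2 truth, 30% of response entries missing
spec = ScenarioSpec(n=500, p=50, k=20, q=10, model="II", kappa=0.3, seed=7)
data, M_star, obs = make_dataset(spec, rep=0)

model = BilinearModel.from_observed(obs, data.X, data.Z)   # lambda = m = 3500
ols = model.fit_ols()                                      # imputed-OLS baseline
res = model.fit(method="mala", n_iter=10_000, n_burnin=1_000, seed=1)

print(res.summary())
print(f"Pred (imputed OLS): {pred_error(ols.params, M_star, data.X, data.Z):.4f}")
print(f"Pred (MALA):        {pred_error(res.params, M_star, data.X, data.Z):.4f}")
print(f"Nmse (MALA):        {nmse(res.params, M_star):.4f}")
```

prints

```
Quasi-Bayesian bilinear regression results
==============================================
method:            MALA
coefficient shape: 50 x 20
observations:      3500 (observed entries)
lambda:            3500
tau:               1
truncation C:      inf
effective rank:    3  (top singular values: 60.116, 27.258, 3.176, 2.493)
iterations:        10000 (burn-in 1000)
acceptance rate:   0.431
step size:         1.302e-05
diverged:          False

Pred (imputed OLS): 10.9855
Pred (MALA):        0.1522
Nmse (MALA):        0.4499
```

The posterior-mean coefficient concentrates on the dominant rank-2
structure (two large singular values, the rest shrunk), and its prediction
error per cell (`Pred = ||X(M̂−M*)Z||_F²/(nq)`, here 0.15) is two orders of
magnitude below the imputation-based OLS baseline (11.0): the rank-2
completion cannot represent the full-rank part of the signal, while the
quasi-posterior works directly on the observed entries. `Nmse ≈ 0.45`
reflects that the component of `M*` outside the row space of `Z` is not
identifiable from `XMZ` for any method.

A command-line interface mirrors the library: `qbimc simulate`,
`qbimc fit`, `qbimc experiment --table 1..4`, and `qbimc theory` (see
`qbimc --help`).

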