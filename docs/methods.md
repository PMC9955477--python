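# Methods

This note documents the statistical model, the samplers, the synthetic
data generator and the numerical choices made in `qbimc`, in the spirit of
a package vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and quasi-posterior

The bilinear regression model is `Y = X M* Z + E` with `Y` n×q, `X` n×p,
`Z` k×q and `M*` p×k, noise `E` zero-mean with independent entries. The
working assumption is that `M*` is exactly or approximately low rank:
a latent process drives the responses through both the between-individuals
structure (`X`) and the within-individuals structure (`Z`).

Rather than a parametric likelihood, inference uses the Gibbs
(quasi-)posterior

    rho_lambda(dM) ∝ exp(-lambda r(M)) pi(dM),

where the empirical risk is the mean squared error of the truncated
predictor `Pi_C(XMZ)` (entrywise clamp to [-C, C]):

* full response:      `r(M) = ||Y - Pi_C(XMZ)||_F² / (nq)`;
* observed entries:   `r'(M) = (1/m) Σ_i (Y_i - Pi_C(XMZ)_{I_i})²` over m
  index/value pairs `(I_i, Y_i)`; duplicate indices (the with-replacement
  observation model) each contribute a residual.

The truncation bound C exists to control predictions under heavy-tailed
noise; in practice (and in all simulation settings here) the chain never
visits the clamp region, so C defaults to +∞ and any finite value is
accepted through configuration. With a finite C, clamped cells get a zero
data-gradient (the exact subgradient of the clamped square loss).

The prior is the spectral scaled Student distribution
`pi(M) ∝ det(tau² I_p + M Mᵀ)^(-(p+k+2)/2)`, equivalently a product of
scaled Student factors in the singular values of M. It is used only
unnormalized. The (p+k+2)/2 exponent is the only reading under which the
determinant form and the printed singular-value product agree
dimensionally (the identity matrix in the determinant must be p×p, and the
product runs over min(p, k) singular values; leftover `tau²` factors are
absorbed into the normalizing constant). Both forms are implemented and
cross-checked in the tests.

Parameters and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `lambda` | inverse temperature | nq (full) / m (observed) | the simulation protocol's choice; `lambda = nq/(2σ²)` would match a Gaussian likelihood exactly |
| `tau` | prior scale on singular values | 1 | the simulation protocol's choice; the theory module computes the bound-optimal τ* for users who want it |
| `C` | sup-norm bound on the signal | +∞ | truncation is a proof device; no finite C is stated for the studies |

## Samplers

Both chains share the Langevin proposal
`M' = M + h ∇log rho(M) + sqrt(2h) N` with iid standard normal `N`:

* **LMC** (unadjusted) applies the proposal directly. It is biased at
  finite h and can explode for large h.
* **MALA** corrects it by Metropolis–Hastings with the asymmetric Gaussian
  proposal density `q(x'|x) ∝ exp(-||x' - x - h ∇log rho(x)||_F² / (4h))`,
  making the quasi-posterior the exact stationary law.

The drift is written here in ascent form (`+ h ∇log rho`). A descent sign
on the gradient of the log-density would climb the *negative* potential
and diverge; the ascent form is the standard Langevin discretization that
targets `rho`, and the proposal density used in the acceptance ratio
carries the matching sign.

Step-size policy: `h` starts at `0.5 / L`, where `L` bounds the gradient's
Lipschitz constant by `(2λ/denom)·c_max·eig_max(XᵀX)·eig_max(ZZᵀ) +
(p+k+2)/τ²` (c_max = largest per-cell observation count). During burn-in,
`h` is adapted multiplicatively, `h ← h·exp(0.05(α - 0.5))`, toward a 0.5
acceptance rate, and frozen afterwards so the post-burn-in MALA kernel
satisfies detailed balance. The LMC chain uses the adjusted kernel during
burn-in (which both tunes `h` and prevents early explosions) and then runs
unadjusted at `0.1·h`, reflecting that the unadjusted discretization needs
a smaller step for comparable accuracy; it is documented as approximate.
A non-finite state triggers a restart from the initial point with `h`
halved, up to five times, after which the result is flagged `diverged`;
diverged replications are excluded from aggregates and counted.

Chains are initialized at the OLS (or imputed-OLS) estimator. The
estimator fed to all error metrics is the post-burn-in chain mean of `M`;
the back-projection of the mean predictor,
`(XᵀX)⁺ Xᵀ (mean predictor) Zᵀ (ZZᵀ)⁺`, is available as an alternative
(`BilinearResults.params_from_predictor`) — the two coincide whenever `X`
has full column rank and `Z` full row rank and C = ∞.

Reproducibility: each chain draws its noise from a Philox counter-based
generator keyed by the chain seed (restarts re-key deterministically), so
identical configurations give bitwise-identical results.

Computation: with C = ∞ and a full response, risk and gradient are
evaluated through the Gram sufficient statistics `XᵀX`, `ZZᵀ`, `XᵀYZᵀ`,
so a chain step costs O(p²k + pk²) regardless of n and q. The
observed-entry variant aggregates duplicates into per-cell counts and
sums, so its cost per step is one n×q predictor pass plus the same Gram
algebra.

## Baselines

* **Generalized OLS**: `(XᵀX)⁺ Xᵀ Y Zᵀ (ZZᵀ)⁺` with Moore–Penrose
  pseudoinverses (total, also for rank-deficient designs; singular values
  below `max(dim)·eps·s_max` are treated as zero, numpy's default).
* **Hard-impute + OLS**: with missing entries, `Y` is completed by
  iterative rank-r SVD — fill missing cells (observed mean by default,
  zero-fill available), alternate best rank-r approximation with
  restoration of observed cells until the imputed cells change by less
  than `tol = 1e-9` in relative Frobenius norm (at most 500 iterations;
  non-convergence returns the best iterate with a warning). Observed cells
  are passed through exactly. The rank defaults to 2, the low-rank
  component of both generator models; a soft-thresholding variant (shrink
  all singular values by the (r+1)-th) is available as a sensitivity flag.
  The surrogate objective `||Y_filled - A_r||_F` is non-increasing along
  the alternation, which the tests assert.

The choice of rank 2 for Model II deserves a remark: the Model II
coefficient is full rank (dominant rank-2 part plus a small full-rank
perturbation), so "the true rank" is ambiguous there. Rank 2 — the
dominant structure — is the default and is configurable. Either way the
completion cannot represent the perturbation's contribution `XUZ` to the
signal (per-cell variance ≈ 0.1·p·k), which is why imputation-based OLS
degrades sharply on Model II while the quasi-posterior, which never
imputes, does not. Note also that this package's deterministic hard-impute
is a *stronger* baseline than soft-thresholding implementations with
default penalties; comparisons against published numbers for
imputation-based OLS should expect our baseline to be better in the
exactly low-rank setting (Model I), where rank-2 completion is
well-specified.

## Theoretical constants

For sub-exponential noise (`E|E|^j ≤ σ² j! ξ^(j-2)/2`) the theory module
computes `C1 = 8(σ² + C²)`, `C2 = 64 C max(ξ, C)`,
`τ* = C1(k+p)/(N_inner ||X||_F² ||Z||_F²)` and
`λ* = N min(1/(2C2), δ/[C1(1+δ)])`, with `(N_inner, N) = (nkq, nq)` for
the full model and `(mkp, m)` for matrix completion, plus the
high-probability oracle radius at rank r

    (C1(1+δ)²/δ)·[4r(k+p+2)·log(1 + ||X||_F||Z||_F||M̄||_F /
        (C1·sqrt(N_inner·r(k+p)))) + (k+p+2)·log(2/ε)] / N.

Two points were genuinely open and are resolved as follows. First,
whether the printed τ* is a scale or a squared scale: the ratio is taken
verbatim as the scale, with a `tau_star_sqrt` flag for the other reading.
Second, the exact grouping of the radius' logarithm in the source
typography: the implementation places the whole sample-size factor
`sqrt(N_inner·r(k+p))` under the logarithm's denominator, the reading
consistent with the overall `r(k+p)/N` rate and with the τ* ratio; the
radius' monotonicity properties (increasing in r, ||M̄||_F and 1/ε,
decreasing in sample size) hold under it and are property-tested. At
`r = 0` the convention `0·log(1+0/0) = 0` applies and the signal norm must
be zero. These constants are reporting/tuning aids; the simulation
defaults (λ = sample size, τ = 1) do not use them.

## Synthetic data generator

The generator reproduces the simulation designs the package is studied
under:

* `X`, `Z`: iid standard normal entries.
* Model I: `M* = B1 B2ᵀ`, `B1` p×2, `B2` k×2, iid standard normal — rank
  ≤ 2 exactly; entry variance 2.
* Model II: `M* = 2 B1 B2ᵀ + U` with `U` iid normal with **variance** 0.1
  (sd √0.1 ≈ 0.316). The notation `N(0, 0.1)` is read as variance by
  mathematical convention; a flag switches to the sd-0.1 reading, and the
  reported error summaries are insensitive to the choice at the printed
  precision.
* Responses: `Y = X M* Z + E`, `E` iid N(0, σ²), σ = 1 by default.
* Missingness: uniform-without-replacement removal of a fraction κ of the
  nq cells (exactly `round((1-κ)nq)` distinct cells remain), or m iid
  uniform draws with replacement — the observation model under which the
  IMC theory is stated.

Every generator is a pure function of (spec, seed); replication r uses
seed `base + r`, so tables are reproducible cell by cell. The reference
study grid fixes q = 10, k = 20 and varies n ∈ {100, 1000},
p ∈ {10, 100}, κ ∈ {0, 10%, 30%}.

What the generator does *not* emulate: correlated or heavy-tailed designs,
non-Gaussian (merely sub-exponential) noise, non-uniform entry-sampling
distributions, and missingness that depends on the signal. Passing tests
therefore demonstrate correctness of the machinery and calibration under
the idealized Gaussian designs, not robustness of the estimator on real
screens.

## Error metrics and analytic anchors

Per replication, for an estimate `M̂` of `M*`:
`Est = ||M̂-M*||_F²/(pk)`, `Nmse = ||M̂-M*||_F²/||M*||_F²`,
`Pred = ||X(M̂-M*)Z||_F²/(nq)`; `Nmse·||M*||_F² = Est·pk` identically.

Two closed forms anchor the harness against silent miscalibration:

* OLS prediction error: `E[Pred] = σ²·rank(X)·q/(nq)` (= σ²p/n for
  n > p), giving 0.01, 0.1 and 1.0 at the three reference design sizes.
* OLS normalized error: with k = 20 > q = 10, the component of `M*`
  outside the row space of `Z` is invisible to the model, so
  `Nmse → (k-q)/k = 0.5` for isotropic `M*` at large n — no estimator of
  `M*` from `XMZ` can do better on that component.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the fully observed OLS
scenarios at 100 replications, and the missing-data MALA scenarios
(n = 1000, κ = 30%, Models I and II) at 20 replications with
5,000-iteration chains (1,000 burn-in) — a desk-scale protocol chosen so
the whole suite completes in minutes; the full 100-replication,
10,000-iteration protocol is the package default and is run through the
same code paths (`qbimc experiment --table .. --reps 100`). Monte Carlo
checks of the samplers use 8 independent chains on a 2×2 Gaussian target
and compare means/covariances at 3 between-chain standard errors.

## Known limitations

* LMC is unadjusted and therefore biased at finite step size; it is
  provided as the cheaper, approximate option and for methodological
  comparison. MALA is the reference sampler.
* The step-size heuristic assumes the quadratic data term dominates; for
  extremely small λ with a tight prior the initial h can be conservative
  (burn-in adaptation compensates).
* Directions of `M` in the null space of `Z` (k > q) or of `X` (p > n)
  are identified only through the prior; chain averages for those
  components mix slowly and carry prior-scale uncertainty. Prediction
  errors are unaffected.
* The oracle-bound radius reflects one reading of ambiguous source
  typography (see above); it is a reporting aid, not a certified bound.
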