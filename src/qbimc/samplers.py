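"""Langevin Monte Carlo samplers for the quasi-posterior.

Two chains are provided over the same proposal mechanics:

* LMC — the unadjusted Langevin algorithm
  ``M <- M + h grad log rho(M) + sqrt(2h) N`` with iid standard normal noise
  matrices N.  Biased at finite h, and can explode when h is too large.
* MALA — the same proposal corrected by a Metropolis–Hastings accept/reject
  step with the asymmetric Gaussian proposal density, which makes the
  quasi-posterior the exact stationary law.

The step size is adapted multiplicatively during burn-in toward a target
acceptance rate (0.5 by default) and frozen afterwards, so the post-burn-in
MALA kernel satisfies detailed balance.  The LMC step is a fixed fraction
(default 0.1) of the MALA-tuned step, reflecting that the unadjusted chain
needs a smaller h for comparable accuracy.  On divergence the chain restarts
from the initial state with h halved, a bounded number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .core import project_entries
from .quasi_posterior import QuasiPosterior

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "lmc_step",
    "mala_proposal_logdensity",
    "mala_acceptance",
    "default_step_size",
    "run_chain",
    "tune_step_size",
]


@dataclass
class SamplerConfig:
    """Run-length, step-size and adaptation settings for one chain."""

    n_iter: int = 10_000
    n_burnin: int = 1_000
    seed: int = 0
    h: float | None = None          # None: curvature-based default
    target_accept: float = 0.5
    adapt: bool = True
    adapt_rate: float = 0.05        # multiplicative log-step per iteration
    lmc_factor: float = 0.1         # LMC step as a fraction of the MALA-tuned h
    max_restarts: int = 5
    record_trace: bool = False
    store_every: int = 0            # >0: keep every store_every-th post-burn-in draw

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.h is not None and not self.h > 0:
            raise ValueError(f"step size h must be positive, got {self.h}")


@dataclass
class ChainResult:
    """Post-burn-in summaries of one Langevin chain."""

    mean_M: np.ndarray
    mean_predictor: np.ndarray
    acceptance_rate: float
    h_final: float
    n_iter: int
    n_burnin: int
    diverged: bool = False
    n_restarts: int = 0
    trace: list = field(default_factory=list, repr=False)
    samples: list = field(default_factory=list, repr=False)

    def trace_to_csv(self, path) -> None:
        """Write the per-iteration (log-posterior, accepted) trace as CSV."""
        import pandas as pd

        pd.DataFrame(self.trace, columns=["iteration", "log_posterior", "accepted"]) \
            .to_csv(path, index=False)


def lmc_step(M, grad, h: float, noise) -> np.ndarray:
    """One Langevin update M + h*grad + sqrt(2h)*noise (deterministic in noise)."""
    if not h > 0:
        raise ValueError(f"step size h must be positive, got {h}")
    M = np.asarray(M, dtype=float)
    return M + h * np.asarray(grad, dtype=float) + np.sqrt(2.0 * h) * np.asarray(noise, dtype=float)


def mala_proposal_logdensity(M_to, M_from, grad_at_from, h: float) -> float:
    """Unnormalized log proposal density q(M_to | M_from).

    The proposal is Gaussian with mean M_from + h*grad and covariance 2h I;
    the normalization cancels in the acceptance ratio.
    """
    if not h > 0:
        raise ValueError(f"step size h must be positive, got {h}")
    D = np.asarray(M_to, dtype=float) - np.asarray(M_from, dtype=float) \
        - h * np.asarray(grad_at_from, dtype=float)
    return float(-np.sum(D * D) / (4.0 * h))


def mala_acceptance(logpost_cur: float, logpost_prop: float,
                    logq_fwd: float, logq_rev: float) -> float:
    """Metropolis–Hastings acceptance probability, computed in log space."""
    vals = (logpost_cur, logpost_prop, logq_fwd, logq_rev)
    if any(np.isnan(v) for v in vals):
        raise ValueError("NaN in acceptance inputs")
    # grouped so an identical proposal gives a ratio of exactly 1
    log_ratio = (logpost_prop - logpost_cur) + (logq_rev - logq_fwd)
    if log_ratio >= 0:
        return 1.0
    return float(np.exp(log_ratio))


def default_step_size(spec: QuasiPosterior) -> float:
    """Curvature-based initial step: 0.5 / (Lipschitz bound of the gradient).

    The data term's Hessian is bounded by (2 lambda / denom) * c_max *
    eigmax(X^T X) * eigmax(Z Z^T) (c_max = largest per-cell observation
    count), and the prior contributes at most (p+k+2)/tau^2.  Burn-in
    adaptation refines this starting point.
    """
    lx = float(np.linalg.eigvalsh(spec._XtX)[-1])
    lz = float(np.linalg.eigvalsh(spec._ZZt)[-1])
    cmax = float(spec._W.max()) if spec.obs is not None else 1.0
    L = 2.0 * spec.lam / spec._denom * cmax * lx * lz
    L += (spec.p + spec.k + 2) / spec.prior.tau**2
    return 0.5 / L


def _safe_value_and_grad(spec, M):
    """Evaluate the target; numeric breakdown (overflowed states) reads as
    a zero-density region rather than an exception."""
    if not np.all(np.isfinite(M)):
        return -np.inf, np.zeros_like(M)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            lp, g = spec.value_and_grad(M)
    except (ValueError, np.linalg.LinAlgError, linalg.LinAlgError):
        return -np.inf, np.zeros_like(M)
    if not np.isfinite(lp) or not np.all(np.isfinite(g)):
        return -np.inf, np.zeros_like(M)
    return lp, g


def _rng_for(seed: int, restart: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(restart,))
    return np.random.Generator(np.random.Philox(ss))


def run_chain(M0, spec: QuasiPosterior, config: SamplerConfig,
              method: str = "mala") -> ChainResult:
    """Run one LMC or MALA chain targeting ``spec`` and summarize it.

    Both methods adapt h during burn-in using MALA acceptance probabilities
    (the unadjusted chain uses the adjusted kernel during burn-in, then runs
    unadjusted at ``lmc_factor * h``).  Post-burn-in iterations accumulate
    running means of M and of the truncated predictor Pi_C(XMZ).  A
    non-finite state triggers a restart with h halved; after
    ``max_restarts`` failures the result is flagged diverged.
    """
    method = method.lower()
    if method not in ("lmc", "mala"):
        raise ValueError(f"method must be 'lmc' or 'mala', got {method!r}")
    M0 = np.asarray(M0, dtype=float)
    h0 = config.h if config.h is not None else default_step_size(spec)

    for restart in range(config.max_restarts + 1):
        h = h0 / 2**restart
        result = _run_once(M0, spec, config, method, h, restart)
        if not result.diverged:
            return result
    return result


def _run_once(M0, spec, config, method, h, restart) -> ChainResult:
    rng = _rng_for(config.seed, restart)
    shape = M0.shape
    linear_pred = np.isinf(spec.C)

    M = M0.copy()
    lp, g = spec.value_and_grad(M)
    if not np.isfinite(lp):
        raise ValueError("initial state has non-finite log-posterior")

    sum_M = np.zeros_like(M)
    sum_pred = None if linear_pred else np.zeros((spec.X.shape[0], spec.Z.shape[1]))
    n_keep = 0
    n_accept = 0.0
    trace = []
    samples = []
    unadjusted = False

    for it in range(config.n_iter):
        if it == config.n_burnin and method == "lmc":
            # switch to the unadjusted kernel at a fraction of the tuned h
            h *= config.lmc_factor
            unadjusted = True

        noise = rng.standard_normal(shape)
        M_prop = lmc_step(M, g, h, noise)
        lp_prop, g_prop = _safe_value_and_grad(spec, M_prop)

        if not np.all(np.isfinite(M_prop)) or not np.isfinite(lp_prop):
            if unadjusted:
                return ChainResult(M, spec.predictor(M), 1.0, h, config.n_iter,
                                   config.n_burnin, diverged=True, n_restarts=restart)
            alpha = 0.0
            accepted = False
        elif unadjusted:
            alpha = 1.0
            accepted = True
        else:
            logq_fwd = mala_proposal_logdensity(M_prop, M, g, h)
            logq_rev = mala_proposal_logdensity(M, M_prop, g_prop, h)
            alpha = mala_acceptance(lp, lp_prop, logq_fwd, logq_rev)
            accepted = rng.random() < alpha

        if accepted:
            M, lp, g = M_prop, lp_prop, g_prop

        if it < config.n_burnin:
            if config.adapt and not unadjusted:
                h *= np.exp(config.adapt_rate * (alpha - config.target_accept))
        else:
            n_keep += 1
            n_accept += accepted
            sum_M += M
            if sum_pred is not None:
                sum_pred += spec.predictor(M)
            if config.store_every and (it - config.n_burnin) % config.store_every == 0:
                samples.append(M.copy())
        if config.record_trace:
            trace.append((it, lp, int(accepted)))

    mean_M = sum_M / n_keep
    if sum_pred is None:
        # with C = inf the predictor is linear in M, so the mean predictor
        # is exactly X mean(M) Z
        mean_pred = spec.X @ mean_M @ spec.Z
    else:
        mean_pred = sum_pred / n_keep
    acc = 1.0 if method == "lmc" else n_accept / n_keep
    return ChainResult(mean_M, mean_pred, float(acc), float(h), config.n_iter,
                       config.n_burnin, diverged=False, n_restarts=restart,
                       trace=trace, samples=samples)


def tune_step_size(spec: QuasiPosterior, config: SamplerConfig,
                   method: str = "mala", M0=None) -> float:
    """Burn-in-only step-size tuning toward the target acceptance rate.

    Runs the MALA adaptation for ``n_burnin`` iterations and returns the
    frozen step (times ``lmc_factor`` for LMC).  With adaptation disabled the
    configured step is returned unchanged.
    """
    factor = config.lmc_factor if method.lower() == "lmc" else 1.0
    if not config.adapt:
        h = config.h if config.h is not None else default_step_size(spec)
        return h * factor
    if M0 is None:
        M0 = np.zeros((spec.p, spec.k))
    probe = replace(config, n_iter=config.n_burnin + 1, record_trace=False)
    res = run_chain(M0, spec, probe, method="mala")
    if res.diverged:
        raise RuntimeError("step-size tuning failed: chain diverged at every retry")
    return res.h_final * factor
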