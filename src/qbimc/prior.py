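"""Spectral scaled Student prior on a p x k coefficient matrix.

The prior density is proportional to ``det(tau^2 I_p + M M^T)^{-(p+k+2)/2}``,
equivalently a product of scaled Student factors ``(tau^2 + s_j(M)^2)^{-(p+k+2)/2}``
over the singular values s_j of M.  Heavy tails on the singular values push
most of them toward zero, so draws are well approximated by low-rank matrices
while a few large singular values remain cheap — the matrix analogue of a
sparsity-inducing scaled Student prior on a vector.

Only the unnormalized log-density and its gradient are needed (for
gradient-based samplers); the normalizing constant is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["PriorConfig", "log_prior", "grad_log_prior", "log_prior_sv"]


@dataclass(frozen=True)
class PriorConfig:
    """Scale ``tau`` and the dimensions (p, k) of the coefficient matrix."""

    tau: float
    p: int
    k: int

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.p < 1 or self.k < 1:
            raise ValueError("dimensions p, k must be >= 1")

    @property
    def exponent(self) -> float:
        # (p + k + 2)/2: the only conformable reading of the determinant form,
        # matching the product over min(p, k) singular values.
        return 0.5 * (self.p + self.k + 2)


def _check_M(M, cfg: PriorConfig) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (cfg.p, cfg.k):
        raise ValueError(f"M must be {cfg.p} x {cfg.k}, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("M contains non-finite entries")
    return M


def _small_gram_chol(M: np.ndarray, tau: float):
    """Cholesky factor of tau^2 I + G where G is the smaller Gram matrix of M.

    Returns (L, side) with side "left" for M M^T (p <= k) or "right" for
    M^T M (k < p); both give the same determinant up to tau^(2|p-k|).
    """
    p, k = M.shape
    if p <= k:
        G = M @ M.T
        side = "left"
    else:
        G = M.T @ M
        side = "right"
    d = G.shape[0]
    L = linalg.cholesky(tau**2 * np.eye(d) + G, lower=True)
    return L, side


def log_prior(M, cfg: PriorConfig) -> float:
    """Unnormalized log-density: -((p+k+2)/2) * log det(tau^2 I_p + M M^T)."""
    M = _check_M(M, cfg)
    p, k = cfg.p, cfg.k
    L, _ = _small_gram_chol(M, cfg.tau)
    logdet_small = 2.0 * np.sum(np.log(np.diag(L)))
    # det(tau^2 I_p + M M^T) = det(tau^2 I_k + M^T M) * tau^(2(p-k)) for p > k
    extra = 2.0 * max(p - min(p, k), 0) * np.log(cfg.tau) if p > k else 0.0
    return float(-cfg.exponent * (logdet_small + extra))


def log_prior_sv(M, cfg: PriorConfig) -> float:
    """Singular-value form of :func:`log_prior` (independent code path).

    -((p+k+2)/2) * [ sum_j log(tau^2 + s_j(M)^2) + (p - min(p,k)) log tau^2 ].
    """
    M = _check_M(M, cfg)
    s = linalg.svd(M, compute_uv=False)
    terms = np.log(cfg.tau**2 + s**2).sum()
    terms += (cfg.p - min(cfg.p, cfg.k)) * 2.0 * np.log(cfg.tau)
    return float(-cfg.exponent * terms)


def grad_log_prior(M, cfg: PriorConfig) -> np.ndarray:
    """Gradient of the unnormalized log-density.

    grad = -(p+k+2) (tau^2 I_p + M M^T)^{-1} M, computed through the smaller
    Gram matrix: for p > k the identity (tau^2 I_p + MM^T)^{-1} M =
    M (tau^2 I_k + M^T M)^{-1} avoids the p x p solve.
    """
    M = _check_M(M, cfg)
    L, side = _small_gram_chol(M, cfg.tau)
    if side == "left":
        G = linalg.cho_solve((L, True), M)
    else:
        G = linalg.cho_solve((L, True), M.T).T
    return -2.0 * cfg.exponent * G
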