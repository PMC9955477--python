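"""Least-squares comparators: generalized OLS and imputation-based OLS.

The generalized OLS estimator for Y = XMZ + E is
``(X^T X)^+ X^T Y Z^T (Z Z^T)^+`` (Moore–Penrose pseudoinverses, so the
estimator is defined for rank-deficient designs).  When the response has
missing entries, OLS is not directly available; the missing cells are first
filled by iterative low-rank SVD imputation (hard-impute) and OLS is applied
to the completed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ImputationConfig", "ols_estimator", "impute_low_rank", "ols_imp_estimator"]


@dataclass
class ImputationConfig:
    """Settings for iterative rank-r SVD imputation.

    rank: target rank of the completion (the generator's low-rank component
    is 2, which is the default used throughout the simulation studies).
    fill: initial value for missing cells — "mean" (observed mean) or "zero".
    soft: use singular-value soft-thresholding at the level of the (rank+1)-th
    singular value instead of hard truncation (sensitivity variant).
    """

    rank: int = 2
    max_iter: int = 500
    tol: float = 1e-9
    fill: str = "mean"
    soft: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.fill not in ("mean", "zero"):
            raise ValueError(f"fill must be 'mean' or 'zero', got {self.fill!r}")


def ols_estimator(X, Y, Z) -> np.ndarray:
    """Generalized OLS: (X^T X)^+ X^T Y Z^T (Z Z^T)^+."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    return np.linalg.pinv(X.T @ X) @ X.T @ Y @ Z.T @ np.linalg.pinv(Z @ Z.T)


def _truncate(A: np.ndarray, cfg: ImputationConfig) -> np.ndarray:
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    r = min(cfg.rank, s.size)
    if cfg.soft:
        thresh = s[r] if r < s.size else 0.0
        s = np.maximum(s - thresh, 0.0)
        return (U * s) @ Vt
    return (U[:, :r] * s[:r]) @ Vt[:r]


def impute_low_rank(Y_obs, cfg: ImputationConfig | None = None) -> np.ndarray:
    """Complete a partially observed matrix by iterative rank-r SVD.

    ``Y_obs`` is dense with NaN marking missing cells.  Missing cells are
    initialized by the fill rule, then the iteration alternates a best
    rank-r approximation with restoration of the observed cells until the
    imputed cells change by less than ``tol`` in relative Frobenius norm.
    Observed cells are returned exactly as given.
    """
    if cfg is None:
        cfg = ImputationConfig()
    Y_obs = np.asarray(Y_obs, dtype=float)
    miss = np.isnan(Y_obs)
    if miss.all():
        raise ValueError("at least one observed entry is required")
    if not miss.any():
        return Y_obs.copy()
    if cfg.rank > min(Y_obs.shape):
        raise ValueError(f"rank {cfg.rank} exceeds min matrix dimension")

    Y = Y_obs.copy()
    Y[miss] = 0.0 if cfg.fill == "zero" else Y_obs[~miss].mean()
    prev = Y[miss].copy()
    for _ in range(cfg.max_iter):
        A = _truncate(Y, cfg)
        Y = np.where(miss, A, Y_obs)
        cur = Y[miss]
        denom = max(float(np.linalg.norm(prev)), 1e-300)
        if float(np.linalg.norm(cur - prev)) / denom < cfg.tol:
            break
        prev = cur.copy()
    else:
        warnings.warn("low-rank imputation did not converge; returning best iterate",
                      RuntimeWarning)
    return Y


def ols_imp_estimator(X, Y_obs, Z, cfg: ImputationConfig | None = None) -> np.ndarray:
    """Generalized OLS on the low-rank-imputed response (missing cells NaN)."""
    return ols_estimator(X, impute_low_rank(Y_obs, cfg), Z)
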