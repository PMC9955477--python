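"""Tempered empirical risks and the quasi-posterior (Gibbs posterior).

The quasi-posterior replaces the likelihood with a tempered empirical risk:

    rho_lambda(dM) ∝ exp(-lambda * r(M)) pi(dM)

where r is the mean squared error of the truncated predictor Pi_C(XMZ) —
over all n*q response cells when Y is fully observed, or over the m observed
entries in the inductive-matrix-completion setting — and pi is the spectral
scaled Student prior.  lambda is the inverse temperature; lambda = nq/(2 sigma^2)
recovers the Gaussian-likelihood posterior.

:class:`QuasiPosterior` bundles the data variant, lambda and the prior, and
exposes the (unnormalized) log-density, its gradient, and a fused
``value_and_grad`` used by the Langevin samplers.  When C is infinite and the
response is fully observed, risk and gradient are evaluated through the
Gram-matrix sufficient statistics (X^T X, Z Z^T, X^T Y Z^T), so the per-step
cost is independent of n and q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BilinearDataset, ObservedEntries, project_entries
from .prior import PriorConfig, grad_log_prior, log_prior

__all__ = [
    "QuasiPosterior",
    "empirical_risk_full",
    "empirical_risk_observed",
    "log_quasi_posterior",
    "grad_log_quasi_posterior",
    "posterior_mean_predictor",
    "coefficient_from_predictor",
]


def empirical_risk_full(M, data: BilinearDataset) -> float:
    """Mean squared error ||Y - Pi_C(XMZ)||_F^2 / (n q) over all cells."""
    M = np.asarray(M, dtype=float)
    T = data.X @ M @ data.Z
    R = data.Y - project_entries(T, data.C)
    return float(np.sum(R * R) / (data.n * data.q))


def empirical_risk_observed(M, X, Z, obs: ObservedEntries, C: float = np.inf) -> float:
    """Mean squared error over the m observed entries.

    Duplicate (row, col) observations each contribute their own residual,
    matching the with-replacement observation model.
    """
    M = np.asarray(M, dtype=float)
    T = project_entries(np.asarray(X) @ M @ np.asarray(Z), C)
    resid = obs.values - T[obs.rows, obs.cols]
    return float(np.sum(resid * resid) / obs.m)


class QuasiPosterior:
    """The tempered quasi-posterior over p x k coefficient matrices.

    Parameters
    ----------
    data
        Either a :class:`BilinearDataset` (full response) or a tuple
        ``(X, Z, ObservedEntries)`` for inductive matrix completion.
    lam
        Inverse temperature lambda > 0.
    prior
        Prior configuration; dimensions must match the designs.
    C
        Truncation bound for the observed-entries variant (the full-data
        variant carries C inside the dataset).
    """

    def __init__(self, data, lam: float, prior: PriorConfig, C: float = np.inf):
        if not lam >= 0:
            raise ValueError(f"lambda must be nonnegative, got {lam}")
        self.lam = float(lam)
        self.prior = prior
        if isinstance(data, BilinearDataset):
            self.dataset = data
            self.obs = None
            self.X, self.Z = data.X, data.Z
            self.C = data.C
            self._denom = data.n * data.q
        else:
            X, Z, obs = data
            if not isinstance(obs, ObservedEntries):
                raise TypeError("observed-data variant expects (X, Z, ObservedEntries)")
            self.dataset = None
            self.obs = obs
            self.X = np.asarray(X, dtype=float)
            self.Z = np.asarray(Z, dtype=float)
            if not C > 0:
                raise ValueError(f"C must be positive, got {C}")
            self.C = float(C)
            self._denom = obs.m
            self._W, self._S = obs.counts_and_sums()
            self._y2 = float(np.sum(obs.values**2))
        p, k = self.X.shape[1], self.Z.shape[0]
        if (prior.p, prior.k) != (p, k):
            raise ValueError(
                f"prior dimensions {(prior.p, prior.k)} do not match designs {(p, k)}"
            )
        self.p, self.k = p, k
        # Gram sufficient statistics; with C = inf and a full response these
        # make risk/gradient evaluation independent of n and q.
        self._XtX = self.X.T @ self.X
        self._ZZt = self.Z @ self.Z.T
        if self.dataset is not None:
            self._G1 = self.X.T @ self.dataset.Y @ self.Z.T
            self._y2 = float(np.sum(self.dataset.Y**2))

    # -- empirical risk -----------------------------------------------------

    def risk(self, M) -> float:
        M = np.asarray(M, dtype=float)
        if self.dataset is not None:
            if np.isinf(self.C):
                quad = float(np.sum((self._XtX @ M) * (M @ self._ZZt)))
                return (self._y2 - 2.0 * float(np.sum(M * self._G1)) + quad) / self._denom
            return empirical_risk_full(M, self.dataset)
        T = self.X @ M @ self.Z
        Tc = project_entries(T, self.C)
        return (self._y2 - 2.0 * float(np.sum(self._S * Tc))
                + float(np.sum(self._W * Tc * Tc))) / self._denom

    # -- log-density and gradient -------------------------------------------

    def logpdf(self, M) -> float:
        """Unnormalized log quasi-posterior -lambda r(M) + log pi(M)."""
        return -self.lam * self.risk(M) + log_prior(M, self.prior)

    def grad(self, M) -> np.ndarray:
        return self.value_and_grad(M)[1]

    def value_and_grad(self, M) -> tuple[float, np.ndarray]:
        """Fused evaluation of the log-density and its gradient.

        At a clamped cell (|XMZ| > C) the square loss is locally flat in M,
        so the data gradient of that cell is exactly zero.
        """
        M = np.asarray(M, dtype=float)
        scale = 2.0 * self.lam / self._denom
        if self.dataset is not None and np.isinf(self.C):
            A = self._XtX @ M @ self._ZZt
            quad = float(np.sum(M * A))
            risk = (self._y2 - 2.0 * float(np.sum(M * self._G1)) + quad) / self._denom
            g_data = scale * (self._G1 - A)
        else:
            T = self.X @ M @ self.Z
            Tc = project_entries(T, self.C)
            inside = np.abs(T) <= self.C if np.isfinite(self.C) else None
            if self.dataset is not None:
                R = self.dataset.Y - Tc
                risk = float(np.sum(R * R)) / self._denom
            else:
                risk = (self._y2 - 2.0 * float(np.sum(self._S * Tc))
                        + float(np.sum(self._W * Tc * Tc))) / self._denom
                R = self._S - self._W * Tc
            if inside is not None:
                R = np.where(inside, R, 0.0)
            g_data = scale * (self.X.T @ (R @ self.Z.T))
        lp = -self.lam * risk + log_prior(M, self.prior)
        g = g_data + grad_log_prior(M, self.prior)
        return lp, g

    def predictor(self, M) -> np.ndarray:
        """Truncated predictor Pi_C(X M Z) on the full n x q grid."""
        return project_entries(self.X @ np.asarray(M, dtype=float) @ self.Z, self.C)


def log_quasi_posterior(M, spec: QuasiPosterior) -> float:
    return spec.logpdf(M)


def grad_log_quasi_posterior(M, spec: QuasiPosterior) -> np.ndarray:
    return spec.grad(M)


def posterior_mean_predictor(samples, X, Z, C: float = np.inf) -> np.ndarray:
    """Monte Carlo estimate of the truncated posterior-mean predictor.

    Averages Pi_C(X M Z) over posterior draws M.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("at least one posterior sample is required")
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    acc = np.zeros((X.shape[0], Z.shape[1]))
    for M in samples:
        acc += project_entries(X @ np.asarray(M, dtype=float) @ Z, C)
    return acc / len(samples)


def coefficient_from_predictor(P_hat, X, Z) -> np.ndarray:
    """Back-project a predictor matrix to coefficient space.

    Returns (X^T X)^+ X^T P_hat Z^T (Z Z^T)^+; with invertible Gram matrices
    this is the plain-inverse back-projection, and the pseudoinverse makes
    the operation total for rank-deficient designs.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    P_hat = np.asarray(P_hat, dtype=float)
    left = np.linalg.pinv(X.T @ X) @ X.T
    right = Z.T @ np.linalg.pinv(Z @ Z.T)
    return left @ P_hat @ right
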