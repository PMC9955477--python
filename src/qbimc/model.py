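"""Model/Results interface for quasi-Bayesian bilinear regression.

:class:`BilinearModel` is built from the data (a full response or observed
triplets plus the two design matrices) and holds the modelling choices
(inverse temperature lambda, prior scale tau, truncation bound C).  Its
``fit`` method runs a Langevin chain (or a least-squares baseline) and
returns a :class:`BilinearResults` carrying the coefficient estimate, the
fitted predictor, chain diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import ImputationConfig, ols_estimator, ols_imp_estimator
from .core import BilinearDataset, ObservedEntries
from .prior import PriorConfig
from .quasi_posterior import QuasiPosterior, coefficient_from_predictor
from .samplers import ChainResult, SamplerConfig, run_chain

__all__ = ["BilinearModel", "BilinearResults"]


class BilinearModel:
    """Quasi-Bayesian low-rank bilinear regression Y = XMZ + E.

    Parameters
    ----------
    endog
        The response: an n x q matrix (full observation) or an
        :class:`ObservedEntries` multiset (inductive matrix completion).
    exog, exog_within
        The between-individuals design X (n x p) and within-individuals
        design Z (k x q).
    lam
        Inverse temperature; default nq (full response) or the observed
        count m — the tempering the simulation protocol uses.
    tau
        Prior scale of the spectral scaled Student prior (default 1).
    C
        Known sup-norm bound on X M* Z; default +inf (no truncation).
    """

    def __init__(self, endog, exog, exog_within, *, lam: float | None = None,
                 tau: float = 1.0, C: float = np.inf):
        X = np.asarray(exog, dtype=float)
        Z = np.asarray(exog_within, dtype=float)
        self.p, self.k = X.shape[1], Z.shape[0]
        self.prior = PriorConfig(tau=tau, p=self.p, k=self.k)
        if isinstance(endog, ObservedEntries):
            self.obs = endog
            self.data = None
            self.X, self.Z, self.C = X, Z, float(C)
            self.nobs = endog.m
        else:
            self.obs = None
            self.data = BilinearDataset(X, Z, np.asarray(endog, dtype=float), C=C)
            self.X, self.Z, self.C = self.data.X, self.data.Z, self.data.C
            self.nobs = self.data.n * self.data.q
        self.lam = float(lam) if lam is not None else float(self.nobs)

    @classmethod
    def from_observed(cls, obs: ObservedEntries, exog, exog_within, **kwargs
                      ) -> "BilinearModel":
        return cls(obs, exog, exog_within, **kwargs)

    def quasi_posterior(self) -> QuasiPosterior:
        if self.data is not None:
            return QuasiPosterior(self.data, self.lam, self.prior)
        return QuasiPosterior((self.X, self.Z, self.obs), self.lam, self.prior,
                              C=self.C)

    def fit_ols(self, imputation: ImputationConfig | None = None
                ) -> "BilinearResults":
        """Generalized (or, with missing entries, imputation-based) OLS."""
        if self.data is not None:
            M = ols_estimator(self.X, self.data.Y, self.Z)
            method = "OLS"
        else:
            Y_na = self.obs.to_mask_matrix(fill=np.nan)
            M = ols_imp_estimator(self.X, Y_na, self.Z,
                                  imputation or ImputationConfig())
            method = "OLS_imp"
        pred = self.X @ M @ self.Z
        return BilinearResults(self, M, pred, method=method)

    def fit(self, method: str = "mala", start=None,
            sampler_config: SamplerConfig | None = None, **config_kwargs
            ) -> "BilinearResults":
        """Sample the quasi-posterior and return posterior-mean estimates.

        ``method`` is "mala" or "lmc"; keyword arguments are forwarded to
        :class:`SamplerConfig` (n_iter, n_burnin, seed, h, ...).  The chain
        starts at the OLS (or imputed-OLS) estimator unless ``start`` is
        given.
        """
        method = method.lower()
        if method in ("ols", "ols_imp", "ols-imp"):
            return self.fit_ols()
        cfg = sampler_config if sampler_config is not None \
            else SamplerConfig(**config_kwargs)
        M0 = np.asarray(start, dtype=float) if start is not None \
            else self.fit_ols().params
        chain = run_chain(M0, self.quasi_posterior(), cfg, method=method)
        return BilinearResults(self, chain.mean_M, chain.mean_predictor,
                               method=method.upper(), chain=chain)


class BilinearResults:
    """Fit results: coefficient estimate, predictor and chain diagnostics."""

    def __init__(self, model: BilinearModel, params: np.ndarray,
                 predictor: np.ndarray, method: str,
                 chain: ChainResult | None = None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.predictor = np.asarray(predictor, dtype=float)
        self.method = method
        self.chain = chain

    @property
    def acceptance_rate(self) -> float | None:
        return None if self.chain is None else self.chain.acceptance_rate

    @property
    def diverged(self) -> bool:
        return bool(self.chain is not None and self.chain.diverged)

    def params_from_predictor(self) -> np.ndarray:
        """Back-projection (X^T X)^+ X^T predictor Z^T (Z Z^T)^+ of the
        posterior-mean predictor (alternative coefficient estimator)."""
        return coefficient_from_predictor(self.predictor, self.model.X,
                                          self.model.Z)

    def singular_values(self) -> np.ndarray:
        return np.linalg.svd(self.params, compute_uv=False)

    def effective_rank(self, rtol: float = 0.05) -> int:
        """Number of singular values above rtol times the largest."""
        s = self.singular_values()
        return int(np.sum(s > rtol * s[0])) if s.size else 0

    def summary(self) -> str:
        m = self.model
        s = self.singular_values()
        lines = [
            "Quasi-Bayesian bilinear regression results",
            "=" * 46,
            f"method:            {self.method}",
            f"coefficient shape: {m.p} x {m.k}",
            f"observations:      {m.nobs}"
            + ("" if m.obs is None else " (observed entries)"),
            f"lambda:            {m.lam:g}",
            f"tau:               {m.prior.tau:g}",
            f"truncation C:      {m.C:g}",
            f"effective rank:    {self.effective_rank()}"
            f"  (top singular values: "
            + ", ".join(f"{v:.3f}" for v in s[:4]) + ")",
        ]
        if self.chain is not None:
            lines += [
                f"iterations:        {self.chain.n_iter} "
                f"(burn-in {self.chain.n_burnin})",
                f"acceptance rate:   {self.chain.acceptance_rate:.3f}",
                f"step size:         {self.chain.h_final:.3e}",
                f"diverged:          {self.chain.diverged}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<BilinearResults method={self.method} "
                f"params {self.params.shape}>")
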