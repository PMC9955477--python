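"""Error metrics and the replication harness for the simulation studies.

Three per-replication summaries are reported for an estimator M_hat of M*:

    Est  = ||M_hat - M*||_F^2 / (p k)        (squared error per coefficient)
    Nmse = ||M_hat - M*||_F^2 / ||M*||_F^2   (relative squared error)
    Pred = ||X (M_hat - M*) Z||_F^2 / (n q)  (squared prediction error per cell)

``run_scenario`` draws replications of a scenario, fits the requested
methods (OLS or imputed OLS, plus LMC/MALA chains initialized at that
baseline) and aggregates means and standard deviations across replications.
Defaults follow the simulation protocol: lambda = nq for a fully observed
response and lambda = m (observed-entry count) with missing data; tau = 1;
10,000 iterations with 1,000 burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import ImputationConfig, ols_estimator, ols_imp_estimator
from .prior import PriorConfig
from .quasi_posterior import QuasiPosterior
from .samplers import SamplerConfig, run_chain
from .synthetic import ScenarioSpec, make_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "MethodResult",
    "est_error",
    "nmse",
    "pred_error",
    "run_scenario",
    "format_table",
]

METRICS = ("Est", "Pred", "Nmse")


def est_error(M_hat, M_star) -> float:
    """Squared coefficient error per entry: ||M_hat - M*||_F^2 / (p k)."""
    M_hat = np.asarray(M_hat, dtype=float)
    M_star = np.asarray(M_star, dtype=float)
    if M_hat.shape != M_star.shape:
        raise ValueError(f"shape mismatch: {M_hat.shape} vs {M_star.shape}")
    D = M_hat - M_star
    return float(np.sum(D * D) / M_star.size)


def nmse(M_hat, M_star) -> float:
    """Relative squared coefficient error: ||M_hat - M*||_F^2 / ||M*||_F^2."""
    M_star = np.asarray(M_star, dtype=float)
    denom = float(np.sum(M_star * M_star))
    if denom == 0:
        raise ValueError("M* must be nonzero for the normalized error")
    D = np.asarray(M_hat, dtype=float) - M_star
    return float(np.sum(D * D) / denom)


def pred_error(M_hat, M_star, X, Z) -> float:
    """Squared prediction error per cell: ||X (M_hat - M*) Z||_F^2 / (n q)."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    D = X @ (np.asarray(M_hat, dtype=float) - np.asarray(M_star, dtype=float)) @ Z
    return float(np.sum(D * D) / D.size)


@dataclass
class MethodResult:
    """Per-replication metric vectors and their summary for one method."""

    method: str
    est: np.ndarray
    pred: np.ndarray
    nmse: np.ndarray
    n_diverged: int = 0

    def mean(self, metric: str) -> float:
        return float(np.mean(getattr(self, metric.lower())))

    def sd(self, metric: str) -> float:
        return float(np.std(getattr(self, metric.lower()), ddof=1))


def _fit_chains(M0, qp, sampler_config, methods, rep):
    out = {}
    for method in methods:
        cfg = replace(sampler_config, seed=sampler_config.seed + rep)
        res = run_chain(M0, qp, cfg, method=method.lower())
        out[method] = res
    return out


def run_scenario(spec: ScenarioSpec, methods=("LMC", "MALA", "OLS"),
                 sampler_config: SamplerConfig | None = None,
                 lam: float | None = None, tau: float = 1.0,
                 imputation: ImputationConfig | None = None) -> dict[str, MethodResult]:
    """Run all replications of one scenario and aggregate the error metrics.

    With missing data (kappa > 0 or with-replacement sampling) the OLS
    comparator is replaced by imputed OLS, and the chains are initialized at
    that estimator; otherwise chains start at plain OLS.  Diverged chains
    are excluded from the aggregates and counted.
    """
    if sampler_config is None:
        sampler_config = SamplerConfig()
    if imputation is None:
        imputation = ImputationConfig()
    has_missing = spec.kappa > 0 or spec.missing_mode == "iid_with_replacement"
    methods = ["OLS_imp" if m.upper() == "OLS" and has_missing else m for m in methods]

    chain_methods = [m for m in methods if m.upper() in ("LMC", "MALA")]
    records: dict[str, dict[str, list]] = {
        m: {"est": [], "pred": [], "nmse": [], "div": 0} for m in methods
    }

    prior = PriorConfig(tau=tau, p=spec.p, k=spec.k)
    for rep in range(spec.n_reps):
        data, M_star, obs = make_dataset(spec, rep)
        if has_missing:
            Y_na = obs.to_mask_matrix(fill=np.nan)
            baseline = ols_imp_estimator(data.X, Y_na, data.Z, imputation)
            lam_r = obs.m if lam is None else lam
            qp = QuasiPosterior((data.X, data.Z, obs), lam_r, prior, C=data.C) \
                if chain_methods else None
        else:
            baseline = ols_estimator(data.X, data.Y, data.Z)
            lam_r = data.n * data.q if lam is None else lam
            qp = QuasiPosterior(data, lam_r, prior) if chain_methods else None

        estimates: dict[str, np.ndarray | None] = {}
        for m in methods:
            if m.upper() in ("OLS", "OLS_IMP"):
                estimates[m] = baseline
        if chain_methods:
            chains = _fit_chains(baseline, qp, sampler_config, chain_methods, rep)
            for m, res in chains.items():
                if res.diverged:
                    records[m]["div"] += 1
                    logger.warning("replication %d: %s chain diverged (excluded)",
                                   rep, m)
                    estimates[m] = None
                else:
                    estimates[m] = res.mean_M

        for m, M_hat in estimates.items():
            if M_hat is None:
                continue
            records[m]["est"].append(est_error(M_hat, M_star))
            records[m]["pred"].append(pred_error(M_hat, M_star, data.X, data.Z))
            records[m]["nmse"].append(nmse(M_hat, M_star))
        logger.info("scenario n=%d p=%d kappa=%.2f: replication %d/%d done",
                    spec.n, spec.p, spec.kappa, rep + 1, spec.n_reps)

    return {
        m: MethodResult(m, np.asarray(r["est"]), np.asarray(r["pred"]),
                        np.asarray(r["nmse"]), r["div"])
        for m, r in records.items()
    }


def format_table(results: dict[str, MethodResult] | list, *,
                 decimals: int = 4) -> pd.DataFrame:
    """Render scenario results as a "mean (sd)" table.

    Accepts either one scenario's method->result mapping or a list of
    (label, mapping) pairs; rows are (label, metric), columns are methods.
    """
    if isinstance(results, dict):
        results = [("", results)]
    if not results:
        raise ValueError("no results to format")
    rows = {}
    for label, mapping in results:
        for metric in METRICS:
            key = (label, metric) if label else metric
            rows[key] = {
                m: f"{r.mean(metric):.{decimals}f} ({r.sd(metric):.{decimals}f})"
                for m, r in mapping.items()
            }
    return pd.DataFrame(rows).T
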