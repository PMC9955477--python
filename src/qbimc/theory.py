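"""Theoretical tuning constants and oracle-inequality radii.

For sub-exponential noise with moment constants (sigma, xi) and a known
sup-norm bound C on the signal, the non-asymptotic analysis of the
quasi-posterior mean prescribes

    C1 = 8 (sigma^2 + C^2),   C2 = 64 C max(xi, C),
    tau* = C1 (k+p) / (N_inner ||X||_F^2 ||Z||_F^2),
    lambda* = N min(1/(2 C2), delta / [C1 (1+delta)]),

with (N_inner, N) = (nkq, nq) for the fully observed model and (mkp, m) for
inductive matrix completion, and a high-probability excess-risk radius that
scales like rank(M*) (k+p) log(.) / N.  These are reporting and tuning aids;
the simulation defaults (lambda = sample size, tau = 1) are set elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseMoments",
    "constants_bilinear",
    "constants_imc",
    "oracle_bound_radius",
]


@dataclass(frozen=True)
class NoiseMoments:
    """Sub-exponential moment constants: E|E|^j <= sigma^2 j! xi^(j-2) / 2."""

    sigma: float
    xi: float

    def __post_init__(self) -> None:
        if not self.sigma > 0 or not self.xi > 0:
            raise ValueError("sigma and xi must be positive")


def _base_constants(sigma: float, xi: float, C: float) -> tuple[float, float]:
    C1 = 8.0 * (sigma**2 + C**2)
    C2 = 64.0 * C * max(xi, C)
    return C1, C2


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def constants_bilinear(noise: NoiseMoments, C: float, n: int, p: int, k: int,
                       q: int, frobX: float, frobZ: float, delta: float,
                       tau_star_sqrt: bool = False):
    """(C1, C2, tau*, lambda*) for the fully observed bilinear model.

    ``tau_star_sqrt`` returns sqrt of the printed tau* ratio (the squared-scale
    reading); the default follows the printed formula verbatim.
    """
    _check_positive(C=C, n=n, p=p, k=k, q=q, frobX=frobX, frobZ=frobZ, delta=delta)
    C1, C2 = _base_constants(noise.sigma, noise.xi, C)
    tau_star = C1 * (k + p) / (n * k * q * frobX**2 * frobZ**2)
    if tau_star_sqrt:
        tau_star = np.sqrt(tau_star)
    lambda_star = n * q * min(1.0 / (2.0 * C2), delta / (C1 * (1.0 + delta)))
    return C1, C2, tau_star, lambda_star


def constants_imc(noise: NoiseMoments, C: float, m: int, p: int, k: int,
                  frobX: float, frobZ: float, delta: float,
                  tau_star_sqrt: bool = False):
    """(C1', C2', tau*, lambda'*) for inductive matrix completion.

    Same formulas with the observation count m replacing nq and mkp
    replacing nkq in tau*.
    """
    _check_positive(C=C, m=m, p=p, k=k, frobX=frobX, frobZ=frobZ, delta=delta)
    C1p, C2p = _base_constants(noise.sigma, noise.xi, C)
    tau_star = C1p * (k + p) / (m * k * p * frobX**2 * frobZ**2)
    if tau_star_sqrt:
        tau_star = np.sqrt(tau_star)
    lambda_star_p = m * min(1.0 / (2.0 * C2p), delta / (C1p * (1.0 + delta)))
    return C1p, C2p, tau_star, lambda_star_p


def oracle_bound_radius(C1: float, delta: float, p: int, k: int,
                        sample_size: float, inner_size: float,
                        frobX: float, frobZ: float, frobMbar: float,
                        r: int, epsilon: float) -> float:
    """High-probability radius of the oracle inequality at rank r.

    radius = (C1 (1+delta)^2 / delta) * [ 4 r (k+p+2) *
             log(1 + ||X||_F ||Z||_F ||Mbar||_F / (C1 sqrt(inner_size * r (k+p))))
             + (k+p+2) log(2/epsilon) ] / sample_size

    ``sample_size`` is nq (full data) or m (IMC); ``inner_size`` is nkq or
    mkp respectively.  At r = 0 the signal must vanish (Mbar = 0) and the
    log term reads 0 (the 0 log(1 + 0/0) = 0 convention).
    """
    _check_positive(C1=C1, delta=delta, p=p, k=k, sample_size=sample_size,
                    inner_size=inner_size)
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if r < 0:
        raise ValueError(f"rank r must be >= 0, got {r}")
    if r == 0:
        if frobMbar != 0:
            raise ValueError("r = 0 requires frobMbar = 0")
        log_term = 0.0
    else:
        arg = frobX * frobZ * frobMbar / (C1 * np.sqrt(inner_size * r * (k + p)))
        log_term = 4.0 * r * (k + p + 2) * np.log1p(arg)
    lead = C1 * (1.0 + delta) ** 2 / delta
    return float(lead * (log_term + (k + p + 2) * np.log(2.0 / epsilon)) / sample_size)
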