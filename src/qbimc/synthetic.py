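"""Simulation designs for the bilinear-regression / matrix-completion studies.

The generators reproduce the study conditions used throughout the package:

* Designs X (n x p) and Z (k x q) with iid standard normal entries.
* Coefficient matrices:
  - Model I (exactly low rank): ``M* = B1 B2^T`` with B1 (p x 2), B2 (k x 2)
    iid standard normal, so rank(M*) <= 2 exactly.
  - Model II (approximately low rank): ``M* = 2 B1 B2^T + U`` with U iid
    normal with variance 0.1 (sd sqrt(0.1); a flag switches to the
    sd-0.1 reading).
* Responses ``Y = X M* Z + E`` with iid N(0, sigma^2) noise, sigma = 1 by
  default.
* Missingness: either uniform-without-replacement removal of a fraction
  kappa of the n*q cells, or m iid uniform index draws with replacement
  (the observation model of the theory).

Every generator is a pure function of (spec, seed); replication r of a
scenario uses seed = base_seed + r.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core import BilinearDataset, ObservedEntries

__all__ = [
    "ScenarioSpec",
    "gen_designs",
    "gen_coefficient",
    "gen_response",
    "apply_missingness",
    "make_dataset",
]


@dataclass
class ScenarioSpec:
    """One cell of the simulation grid.

    kappa is the missing rate (0 for the fully observed studies); the
    with-replacement mode instead draws ``m`` iid cell indices.
    """

    n: int = 100
    p: int = 10
    k: int = 20
    q: int = 10
    sigma: float = 1.0
    model: str = "I"
    kappa: float = 0.0
    missing_mode: str = "uniform_without_replacement"
    n_reps: int = 100
    seed: int = 0
    u_sd_reading: bool = False  # Model II: read N(0, 0.1) as sd rather than variance

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.k, self.q) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0 <= self.kappa < 1:
            raise ValueError(f"kappa must lie in [0, 1), got {self.kappa}")
        if self.model not in ("I", "II"):
            raise ValueError(f"model must be 'I' or 'II', got {self.model!r}")
        if self.missing_mode not in ("uniform_without_replacement", "iid_with_replacement"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def _rng(seed: int, stream: str) -> np.random.Generator:
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return np.random.Generator(np.random.Philox(ss))


def gen_designs(spec: ScenarioSpec, seed: int | None = None):
    """Draw the design matrices X (n x p) and Z (k x q), iid standard normal."""
    rng = _rng(spec.seed if seed is None else seed, "designs")
    X = rng.standard_normal((spec.n, spec.p))
    Z = rng.standard_normal((spec.k, spec.q))
    return X, Z


def gen_coefficient(spec: ScenarioSpec, seed: int | None = None) -> np.ndarray:
    """Draw the true coefficient matrix M* (p x k) under Model I or II."""
    rng = _rng(spec.seed if seed is None else seed, "coefficient")
    B1 = rng.standard_normal((spec.p, 2))
    B2 = rng.standard_normal((spec.k, 2))
    if spec.model == "I":
        return B1 @ B2.T
    u_scale = 0.1 if spec.u_sd_reading else np.sqrt(0.1)
    U = u_scale * rng.standard_normal((spec.p, spec.k))
    return 2.0 * B1 @ B2.T + U


def gen_response(X, M_star, Z, sigma: float, seed: int) -> np.ndarray:
    """Y = X M* Z + E with iid N(0, sigma^2) noise."""
    rng = _rng(seed, "response")
    signal = np.asarray(X) @ np.asarray(M_star) @ np.asarray(Z)
    if sigma == 0:
        return signal
    return signal + sigma * rng.standard_normal(signal.shape)


def apply_missingness(Y, kappa_or_m, mode: str = "uniform_without_replacement",
                      seed: int = 0) -> ObservedEntries:
    """Reduce a full response matrix to observed entries.

    * uniform_without_replacement: remove a fraction kappa of the n*q cells
      uniformly at random; exactly round((1-kappa)*n*q) distinct cells remain.
    * iid_with_replacement: draw m iid uniform cell indices (duplicates
      possible), the observation model under which the IMC theory is stated.
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    rng = _rng(seed, "missingness")
    if mode == "uniform_without_replacement":
        kappa = float(kappa_or_m)
        if not 0 <= kappa < 1:
            raise ValueError(f"kappa must lie in [0, 1), got {kappa}")
        n_keep = int(round((1.0 - kappa) * n * q))
        if n_keep < 1:
            raise ValueError("missing rate leaves no observed cells")
        flat = rng.permutation(n * q)[:n_keep]
        rows, cols = np.divmod(flat, q)
        return ObservedEntries(rows, cols, Y[rows, cols], n, q,
                               with_replacement=False)
    if mode == "iid_with_replacement":
        m = int(kappa_or_m)
        if m < 1:
            raise ValueError(f"m must be >= 1, got {m}")
        flat = rng.integers(0, n * q, size=m)
        rows, cols = np.divmod(flat, q)
        return ObservedEntries(rows, cols, Y[rows, cols], n, q,
                               with_replacement=True)
    raise ValueError(f"unknown missingness mode {mode!r}")


def make_dataset(spec: ScenarioSpec, rep: int = 0):
    """Generate one replication: (dataset, M*, observed-or-None).

    Returns a fully observed :class:`BilinearDataset` plus, when kappa > 0
    (or with-replacement mode), the :class:`ObservedEntries` reduction of Y.
    Replication ``rep`` uses seed ``spec.seed + rep``.
    """
    seed = spec.seed + rep
    X, Z = gen_designs(spec, seed)
    M_star = gen_coefficient(spec, seed)
    Y = gen_response(X, M_star, Z, spec.sigma, seed)
    data = BilinearDataset(X, Z, Y)
    obs = None
    if spec.missing_mode == "iid_with_replacement":
        m = int(round((1.0 - spec.kappa) * spec.n * spec.q))
        obs = apply_missingness(Y, m, "iid_with_replacement", seed)
    elif spec.kappa > 0:
        obs = apply_missingness(Y, spec.kappa, "uniform_without_replacement", seed)
    return data, M_star, obs
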