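"""Shared containers and primitives for bilinear regression with side information.

The bilinear (growth-curve / GMANOVA) model is ``Y = X M* Z + E`` with a
between-individuals design ``X`` (n x p), a within-individuals design ``Z``
(k x q) and an unknown coefficient matrix ``M*`` (p x k).  When only a random
subset of the entries of ``Y`` is available the problem becomes inductive
matrix completion; the observed entries are then carried as (row, col, value)
triplets.

Everything downstream (priors, quasi-posteriors, samplers, baselines) works
with the two dataset containers defined here plus two primitives: the
entrywise truncation projection and the sampling-weighted Frobenius norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BilinearDataset",
    "ObservedEntries",
    "SamplingDistribution",
    "project_entries",
    "weighted_frob_norm_sq",
    "read_dense",
    "write_dense",
    "read_observed",
    "write_observed",
]


def _as_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-d array, got ndim={a.ndim}")
    return a


def project_entries(A, C: float) -> np.ndarray:
    """Entrywise truncation of ``A`` to the interval [-C, C].

    This is the orthogonal (Frobenius) projection onto the set of matrices
    with sup-norm at most ``C``.  ``C = inf`` is the identity.
    """
    if not C > 0:
        raise ValueError(f"truncation bound C must be positive, got {C}")
    A = np.asarray(A, dtype=float)
    if not np.isfinite(C):
        return A
    return np.clip(A, -C, C)


def weighted_frob_norm_sq(A, P: "SamplingDistribution | np.ndarray") -> float:
    """Squared Frobenius norm of ``A`` weighted by an entry-sampling law.

    Returns sum_ij P[(i,j)] * A_ij^2.  With the uniform distribution this is
    ||A||_F^2 / (n1*n2).
    """
    A = _as_matrix(A, "A")
    W = P.probabilities if isinstance(P, SamplingDistribution) else np.asarray(P, dtype=float)
    if W.shape != A.shape:
        raise ValueError(f"shape mismatch: A is {A.shape}, P is {W.shape}")
    return float(np.sum(W * A * A))


@dataclass
class SamplingDistribution:
    """Distribution Pi of the random index I over the n x q grid of cells."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        P = _as_matrix(self.probabilities, "probabilities")
        if np.any(P < 0):
            raise ValueError("sampling probabilities must be nonnegative")
        if abs(P.sum() - 1.0) > 1e-12:
            raise ValueError(f"sampling probabilities must sum to 1, got {P.sum()!r}")
        self.probabilities = P

    @classmethod
    def uniform(cls, n: int, q: int) -> "SamplingDistribution":
        return cls(np.full((n, q), 1.0 / (n * q)))


@dataclass
class BilinearDataset:
    """Fully observed bilinear-regression data (Y, X, Z) with truncation bound C.

    C is the known sup-norm bound on X M* Z; it defaults to +inf (no
    truncation), which is how the simulation studies are run.
    """

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    C: float = np.inf

    def __post_init__(self) -> None:
        self.X = _as_matrix(self.X, "X")
        self.Z = _as_matrix(self.Z, "Z")
        self.Y = _as_matrix(self.Y, "Y")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        n, q = self.Y.shape
        if self.X.shape[0] != n:
            raise ValueError(f"X has {self.X.shape[0]} rows but Y has {n}")
        if self.Z.shape[1] != q:
            raise ValueError(f"Z has {self.Z.shape[1]} columns but Y has {q}")
        for name, A in (("X", self.X), ("Z", self.Z), ("Y", self.Y)):
            if not np.all(np.isfinite(A)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.Z.shape[0]


@dataclass
class ObservedEntries:
    """A multiset of observed response entries for inductive matrix completion.

    Triplets are (row, col, value) with 1-based indices in user-facing form;
    internally rows/cols are stored 0-based.  Duplicates are legal only under
    the with-replacement observation model (iid index draws).
    """

    rows: np.ndarray  # 0-based
    cols: np.ndarray  # 0-based
    values: np.ndarray
    n: int
    q: int
    with_replacement: bool = False

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp).ravel()
        self.cols = np.asarray(self.cols, dtype=np.intp).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        m = self.rows.size
        if not (self.cols.size == m == self.values.size):
            raise ValueError("rows, cols and values must have equal length")
        if m < 1:
            raise ValueError("at least one observed entry is required")
        if np.any(self.rows < 0) or np.any(self.rows >= self.n):
            raise ValueError(f"row indices must lie in 1..{self.n}")
        if np.any(self.cols < 0) or np.any(self.cols >= self.q):
            raise ValueError(f"column indices must lie in 1..{self.q}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observed values must be finite")
        if not self.with_replacement:
            flat = self.rows * self.q + self.cols
            if np.unique(flat).size != m:
                raise ValueError(
                    "duplicate (row, col) pairs require with_replacement=True"
                )

    @classmethod
    def from_triplets(cls, triplets, n: int, q: int, *, one_based: bool = True,
                      with_replacement: bool = False) -> "ObservedEntries":
        """Build from an iterable of (row, col, value); indices 1-based by default."""
        arr = np.asarray(list(triplets), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("triplets must be (row, col, value) rows")
        off = 1 if one_based else 0
        return cls(arr[:, 0].astype(np.intp) - off, arr[:, 1].astype(np.intp) - off,
                   arr[:, 2], n, q, with_replacement)

    @property
    def m(self) -> int:
        return self.rows.size

    def counts_and_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell observation counts and per-cell sums of observed values.

        Duplicate observations accumulate, so the empirical risk and its
        gradient cost one n x q pass regardless of m.
        """
        W = np.zeros((self.n, self.q))
        S = np.zeros((self.n, self.q))
        np.add.at(W, (self.rows, self.cols), 1.0)
        np.add.at(S, (self.rows, self.cols), self.values)
        return W, S

    def to_mask_matrix(self, fill=np.nan) -> np.ndarray:
        """Dense n x q matrix with unobserved cells set to ``fill``.

        Duplicates average; useful for imputation-based baselines.
        """
        W, S = self.counts_and_sums()
        Y = np.full((self.n, self.q), float(fill))
        obs = W > 0
        Y[obs] = S[obs] / W[obs]
        return Y


# ---------------------------------------------------------------------------
# plain-text IO: dense CSV (no header) and 1-based coordinate triplets

def read_dense(path) -> np.ndarray:
    """Read a dense matrix from headerless CSV; the token NA marks missing cells."""
    df = pd.read_csv(path, header=None, na_values=["NA"])
    return df.to_numpy(dtype=float)


def write_dense(path, A) -> None:
    A = np.asarray(A, dtype=float)
    pd.DataFrame(A).to_csv(path, header=False, index=False, na_rep="NA")


def read_observed(path, *, with_replacement: bool = False) -> ObservedEntries:
    """Read coordinate-format observations: header line "n q m", then "row col value".

    Indices are 1-based (MatrixMarket coordinate dialect).
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError("first line must be the size header 'n q m'")
        n, q, m = (int(x) for x in header)
        data = np.loadtxt(fh, ndmin=2)
    if data.shape[0] != m:
        raise ValueError(f"header promises {m} triplets but file has {data.shape[0]}")
    return ObservedEntries.from_triplets(data, n, q, with_replacement=with_replacement)


def write_observed(path, obs: ObservedEntries) -> None:
    with open(path, "w") as fh:
        fh.write(f"{obs.n} {obs.q} {obs.m}\n")
        for i, j, v in zip(obs.rows, obs.cols, obs.values):
            fh.write(f"{i + 1} {j + 1} {float(v)!r}\n")
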