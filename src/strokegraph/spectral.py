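"""Graph Laplacians, Chebyshev polynomial filtering, and the dense spectral oracle.

Spectral graph convolution filters a node signal x through a function of
the graph Laplacian L = D - A.  Writing L = U diag(lambda) U^T, a filter
g acts as U g(diag(lambda)) U^T x.  Chebyshev filtering approximates g by
a polynomial in the Laplacian rescaled to spectrum [-1, 1], evaluated with
the three-term recurrence

    T_0(x) = x,  T_1(x) = L~ x,  T_k(x) = 2 L~ T_{k-1}(x) - T_{k-2}(x),

which never materializes powers of L~ nor its eigendecomposition.  The
:class:`SpectralDecomposition` here performs the filtering the slow, exact
way through the eigenbasis; it exists purely as an independent oracle for
the recurrence and is not used by the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "degree_matrix",
    "laplacian",
    "scaled_laplacian",
    "estimate_lmax",
    "cheb_basis_apply",
    "SpectralDecomposition",
]


def degree_matrix(A: np.ndarray) -> np.ndarray:
    """Diagonal degree matrix with D_ii = sum_j A_ij."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError(f"adjacency must be square, got shape {A.shape}")
    return np.diag(A.sum(axis=1))


def laplacian(A: np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D - A (rows sum to zero; PSD)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise InputError("adjacency must be symmetric")
    return degree_matrix(A) - A


def estimate_lmax(M: np.ndarray, n_iter: int = 200, tol: float = 1e-10,
                  seed: int = 0) -> float:
    """Largest eigenvalue of a symmetric PSD matrix by power iteration."""
    M = np.asarray(M, dtype=np.float64)
    n = M.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = M @ v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return 0.0
        v_new = w / nrm
        lam_new = float(v_new @ M @ v_new)
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            return lam_new
        lam, v = lam_new, v_new
    return lam


def scaled_laplacian(A: np.ndarray, normalization: str = "sym",
                     lmax: float | None = None) -> np.ndarray:
    """Laplacian rescaled so its spectrum lies in [-1, 1].

    ``sym``: L_n = D^{-1/2} (D - A) D^{-1/2} with isolated nodes given unit
    degree (their L_n row is zero, so they simply pass their own signal
    through).  ``comb``: L_n = D - A.  Either way the result is
    2 L_n / lambda_max - I; for an edgeless graph this is -I.
    """
    A = np.asarray(A, dtype=np.float64)
    L = laplacian(A)
    if normalization == "sym":
        d = A.sum(axis=1)
        d_safe = np.where(d > 0, d, 1.0)
        inv_sqrt = 1.0 / np.sqrt(d_safe)
        Ln = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    elif normalization == "comb":
        Ln = L
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    if lmax is None:
        # Region graphs are small (N ~ 100), so the exact extreme eigenvalue
        # is affordable and keeps the spectrum strictly inside [-1, 1];
        # estimate_lmax is the iterative alternative for larger graphs.
        lmax = float(np.linalg.eigvalsh(Ln)[-1])
    if lmax <= 1e-12:
        # Edgeless graph: Ln = 0 and any positive scale gives -I.
        lmax = 2.0
    n = A.shape[0]
    return 2.0 * Ln / lmax - np.eye(n)


def cheb_basis_apply(Lt: np.ndarray, x: np.ndarray, order: int) -> list[np.ndarray]:
    """[T_0(L~) x, ..., T_{order-1}(L~) x] via the three-term recurrence."""
    if order < 1:
        raise ConfigurationError("Chebyshev order must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    out = [x]
    if order > 1:
        out.append(Lt @ x)
    for _ in range(2, order):
        out.append(2.0 * (Lt @ out[-1]) - out[-2])
    return out


@dataclass
class SpectralDecomposition:
    """Eigendecomposition L~ = U diag(lambda) U^T -- test oracle only."""

    U: np.ndarray
    Lambda: np.ndarray

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "SpectralDecomposition":
        M = np.asarray(M, dtype=np.float64)
        lam, U = np.linalg.eigh(M)
        return cls(U=U, Lambda=lam)

    def apply_chebyshev(self, x: np.ndarray, k: int) -> np.ndarray:
        """U T_k(diag(lambda)) U^T x with T_k evaluated in closed form.

        Uses T_k(cos t) = cos(k t) on eigenvalues clipped to [-1, 1], so it
        shares no code path with the matrix recurrence it checks.
        """
        tk = np.cos(k * np.arccos(np.clip(self.Lambda, -1.0, 1.0)))
        return self.U @ (tk[:, None] * (self.U.T @ np.asarray(x, dtype=np.float64)))

    def filter(self, x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        """Polynomial filter sum_k c_k U T_k(diag(lambda)) U^T x."""
        out = np.zeros_like(np.asarray(x, dtype=np.float64))
        for k, c in enumerate(coeffs):
            out = out + c * self.apply_chebyshev(x, k)
        return out
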