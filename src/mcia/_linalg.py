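"""Matrix backends shared by the solver.

Blocks are held either as dense ``numpy.ndarray`` or as :class:`SparseLowRank`,
a sparse matrix with an attached low-rank correction ``M = S - L @ R.T``.
The correction absorbs column centering (one rank-1 term) and every deflation
step (one rank-1 term per order), so sparsity of ``S`` is never destroyed.

All helpers in this module run in O(nnz + (n + p) * k) per product, where k is
the number of low-rank terms; no n x n or p x p intermediate is ever formed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, svds

__all__ = [
    "SparseLowRank",
    "as_backend",
    "is_sparse_backend",
    "matvec",
    "rmatvec",
    "colnorms_sq",
    "frob_sq",
    "sigma_max",
    "to_dense",
    "deflate_block_loading",
    "deflate_global_score",
]


class SparseLowRank:
    """Implicit representation of ``S - L @ R.T`` with sparse ``S``.

    Parameters
    ----------
    S : scipy sparse matrix, shape (n, p)
        Sparse base (CSR internally).
    L : ndarray, shape (n, k)
    R : ndarray, shape (p, k)
        Dense low-rank factors; ``k`` may be zero.
    """

    def __init__(self, S, L=None, R=None):
        self.S = sp.csr_matrix(S)
        n, p = self.S.shape
        self.L = np.zeros((n, 0)) if L is None else np.asarray(L, dtype=float)
        self.R = np.zeros((p, 0)) if R is None else np.asarray(R, dtype=float)
        if self.L.ndim != 2 or self.R.ndim != 2 or self.L.shape[1] != self.R.shape[1]:
            raise ValueError("inconsistent low-rank factors")
        if self.L.shape[0] != n or self.R.shape[0] != p:
            raise ValueError("low-rank factor shapes do not match S")

    @property
    def shape(self):
        return self.S.shape

    @property
    def rank_correction(self) -> int:
        return self.L.shape[1]

    def matvec(self, v):
        v = np.asarray(v, dtype=float)
        out = self.S @ v
        if self.rank_correction:
            out = out - self.L @ (self.R.T @ v)
        return np.asarray(out).ravel() if v.ndim == 1 else np.asarray(out)

    def rmatvec(self, u):
        u = np.asarray(u, dtype=float)
        out = self.S.T @ u
        if self.rank_correction:
            out = out - self.R @ (self.L.T @ u)
        return np.asarray(out).ravel() if u.ndim == 1 else np.asarray(out)

    def toarray(self):
        out = self.S.toarray()
        if self.rank_correction:
            out -= self.L @ self.R.T
        return out

    def colnorms_sq(self):
        A = np.asarray(self.S.multiply(self.S).sum(axis=0)).ravel()
        if not self.rank_correction:
            return A
        B = np.asarray((self.S.T @ self.L))            # p x k
        cross = np.sum(B * self.R, axis=1)             # s_j . (L r_j)
        G = self.L.T @ self.L                          # k x k
        quad = np.sum((self.R @ G) * self.R, axis=1)   # ||L r_j||^2
        return A - 2.0 * cross + quad

    def with_update(self, left, right):
        """Return ``self - outer(left, right)`` as a new SparseLowRank."""
        L = np.hstack([self.L, np.asarray(left, dtype=float).reshape(-1, 1)])
        R = np.hstack([self.R, np.asarray(right, dtype=float).reshape(-1, 1)])
        return SparseLowRank(self.S, L, R)

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(
            self.shape, matvec=self.matvec, rmatvec=self.rmatvec, dtype=float
        )


def as_backend(values):
    """Normalize raw block values to ndarray or SparseLowRank."""
    if isinstance(values, SparseLowRank):
        return values
    if sp.issparse(values):
        return SparseLowRank(values)
    return np.asarray(values, dtype=float)


def is_sparse_backend(M) -> bool:
    return isinstance(M, SparseLowRank)


def matvec(M, v):
    if isinstance(M, SparseLowRank):
        return M.matvec(v)
    return M @ v


def rmatvec(M, u):
    if isinstance(M, SparseLowRank):
        return M.rmatvec(u)
    return M.T @ u


def colnorms_sq(M):
    if isinstance(M, SparseLowRank):
        return M.colnorms_sq()
    return np.einsum("ij,ij->j", M, M)


def frob_sq(M) -> float:
    return float(np.sum(colnorms_sq(M)))


def sigma_max(M) -> float:
    """Largest singular value without densifying sparse inputs."""
    n, p = M.shape
    if min(n, p) <= 2 or not isinstance(M, SparseLowRank):
        dense = to_dense(M)
        if dense.size == 0:
            return 0.0
        return float(np.linalg.svd(dense, compute_uv=False)[0])
    s = svds(M.as_linear_operator(), k=1, return_singular_vectors=False)
    return float(s[0])


def to_dense(M):
    if isinstance(M, SparseLowRank):
        return M.toarray()
    return np.asarray(M, dtype=float)


def deflate_block_loading(M, a):
    """``M (I - a a^T)`` — removes loading direction ``a`` from feature space."""
    a = np.asarray(a, dtype=float)
    if isinstance(M, SparseLowRank):
        return M.with_update(M.matvec(a), a)
    return M - np.outer(M @ a, a)


def deflate_global_score(M, u):
    """``(I - u u^T) M`` — removes score direction ``u`` from sample space."""
    u = np.asarray(u, dtype=float)
    if isinstance(M, SparseLowRank):
        return M.with_update(u, M.rmatvec(u))
    return M - np.outer(u, u.T @ M)
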