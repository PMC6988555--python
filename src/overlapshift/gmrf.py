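"""Gaussian Markov random field utilities on lattice graphs.

Structure matrices for intrinsic CAR fields and random-walk smooths, sparse
SPD factorisations (SuperLU) with log-determinants, and a constrained
Gaussian helper implementing conditioning-by-kriging for linear constraints
``C x = 0`` (sum-to-zero fields and the like).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Adjacency

__all__ = [
    "icar_structure",
    "rw_structure",
    "rw_constraint",
    "SPDFactor",
    "ConstrainedGaussian",
    "sample_gmrf",
]


def icar_structure(adjacency: Adjacency) -> sp.csr_matrix:
    """Intrinsic CAR structure matrix R = D - W over active cells.

    Singular (rank deficiency one per connected component); callers add a
    small diagonal jitter and impose a sum-to-zero constraint.
    """
    w = adjacency.matrix
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


def rw_structure(m: int, order: int = 1) -> sp.csr_matrix:
    """Random-walk penalty matrix K = D'D for first/second differences."""
    if order not in (1, 2):
        raise ValueError("random-walk order must be 1 or 2")
    d = sp.eye(m, format="csr")
    for _ in range(order):
        rows = d.shape[0] - 1
        diff = sp.diags([-np.ones(rows), np.ones(rows)], offsets=[0, 1],
                        shape=(rows, d.shape[0]))
        d = (diff @ d).tocsr()
    return (d.T @ d).tocsr()


def rw_constraint(m: int, order: int = 1) -> np.ndarray:
    """Identifiability constraint rows for an RW smooth: sum-to-zero.

    The RW2 null space also contains the linear trend; it is left unconstrained
    (weakly regularised by the diagonal jitter) so monotone covariate effects
    remain representable, matching the usual areal-model convention.
    """
    del order
    return np.ones((1, m)) / m


class SPDFactor:
    """Sparse LU factorisation of a symmetric positive definite matrix.

    Provides solves and the log-determinant (sum of log |diag(U)|, valid for
    SPD matrices under any pivoting).
    """

    def __init__(self, q: sp.spmatrix):
        self.shape = q.shape
        # symmetric-mode minimum-degree ordering: order-of-magnitude less
        # fill than the default for GMRF-structured SPD matrices
        self._lu = spla.splu(q.tocsc(), permc_spec="MMD_AT_PLUS_A",
                             diag_pivot_thresh=0.0,
                             options={"SymmetricMode": True})

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(np.asarray(b, dtype=float))

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(np.abs(self._lu.U.diagonal()))))


class ConstrainedGaussian:
    """Gaussian N(m, Q^{-1}) conditioned on C x = 0.

    ``Q`` sparse precision, ``b`` the linear term (unconstrained mean solves
    Q m = b), ``C`` a dense (k, d) constraint matrix.  Supplies the constrained
    mean, marginal variances of sparse linear functionals, seeded joint
    samples (dense Cholesky, computed lazily), and the small-matrix pieces
    needed for constrained Laplace marginal likelihoods.
    """

    def __init__(self, q: sp.spmatrix, b: np.ndarray, c: np.ndarray,
                 factor: SPDFactor | None = None, e: np.ndarray | None = None):
        self.q = q.tocsc()
        self.b = np.asarray(b, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.e = (np.zeros(self.c.shape[0]) if e is None
                  else np.asarray(e, dtype=float))
        self.factor = factor if factor is not None else SPDFactor(self.q)
        self.mean_unconstrained = self.factor.solve(self.b)
        # Q^{-1} C'  (d, k) and S = C Q^{-1} C'  (k, k)
        self.qinv_ct = self.factor.solve(self.c.T) if self.c.size else \
            np.zeros((self.q.shape[0], 0))
        self.s_cc = self.c @ self.qinv_ct if self.c.size else np.zeros((0, 0))
        self._chol: np.ndarray | None = None

    # -- means and corrections -------------------------------------------
    def correct(self, x: np.ndarray) -> np.ndarray:
        """Project x onto the constraint manifold by kriging."""
        if self.c.size == 0:
            return x
        resid = self.c @ x - self.e
        return x - self.qinv_ct @ np.linalg.solve(self.s_cc, resid)

    @property
    def mean(self) -> np.ndarray:
        return self.correct(self.mean_unconstrained)

    # -- variances -------------------------------------------------------
    def var_linear(self, a: sp.spmatrix) -> np.ndarray:
        """Marginal variances of rows of A under the constrained Gaussian."""
        a = sp.csr_matrix(a)
        x = self.factor.solve(a.T.toarray())          # (d, m)
        var = np.asarray(a.multiply(x.T).sum(axis=1)).ravel()
        if self.c.size:
            aq = a @ self.qinv_ct                      # (m, k)
            var = var - np.einsum("mk,mk->m", aq @ np.linalg.inv(self.s_cc), aq)
        return np.maximum(var, 0.0)

    def marginal_sd(self, idx: np.ndarray) -> np.ndarray:
        sel = sp.csr_matrix(
            (np.ones(len(idx)), (np.arange(len(idx)), idx)),
            shape=(len(idx), self.q.shape[0]),
        )
        return np.sqrt(self.var_linear(sel))

    # -- sampling --------------------------------------------------------
    def _cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol = sla.cholesky(self.q.toarray(), lower=True)
        return self._chol

    def release(self) -> None:
        """Drop the cached dense Cholesky factor (memory)."""
        self._chol = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n joint samples (rows) from the constrained Gaussian."""
        d = self.q.shape[0]
        l = self._cholesky()
        z = rng.standard_normal((d, n))
        u = sla.solve_triangular(l, z, lower=True, trans="T")  # N(0, Q^{-1})
        xs = (self.mean_unconstrained[:, None] + u).T          # (n, d)
        if self.c.size:
            resid = xs @ self.c.T - self.e                     # (n, k)
            xs = xs - resid @ np.linalg.solve(self.s_cc, self.qinv_ct.T)
        return xs


def sample_gmrf(q: sp.spmatrix, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n fields (rows) from N(0, Q^{-1}) for a dense-manageable Q."""
    l = sla.cholesky(sp.csc_matrix(q).toarray(), lower=True)
    z = rng.standard_normal((q.shape[0], n))
    return sla.solve_triangular(l, z, lower=True, trans="T").T
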