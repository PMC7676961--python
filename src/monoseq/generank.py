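"""GeneRank: network-weighted expression values.

For one sample with expression vector ``e`` over ``p`` genes, the GeneRank
vector ``r`` solves the PageRank-style linear system

    (I - d W D^{-1}) r = (1 - d) e

where ``W`` is the symmetric 0/1 interaction adjacency, ``D`` the diagonal
degree matrix and ``d`` in [0, 1) the damping parameter trading off the
expression values (d=0 gives r=e) against network connectivity.  Isolated
genes (degree 0) get a unit diagonal in ``D`` so the system stays
well-posed; their W column is all-zero, so their solution is
``r = (1 - d) e`` regardless of the convention.

Solving once per sample and stacking the columns turns a genes-by-samples
expression matrix into the weighted matrix the downstream monotone-trend
screen consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import GeneNetwork

__all__ = ["GeneRankMatrix", "generank_sample", "generank_matrix", "system_matrix"]

#: network size below which a dense LU factorisation is used
_DENSE_CUTOFF = 500


@dataclass
class GeneRankMatrix:
    """Genes-by-samples matrix of GeneRank vectors (one solve per column)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    damping: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GeneRank values contain non-finite entries")


def system_matrix(net: GeneNetwork, d: float) -> sp.csr_matrix:
    """The sparse system matrix ``I - d W D~^{-1}`` for damping ``d``.

    ``D~`` is the degree matrix with zeros on the diagonal replaced by 1
    (isolated genes), which only normalises an all-zero column of W.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError(
            f"damping d={d} outside [0, 1); at d=1 the system is singular"
        )
    p = net.n_genes
    deg = np.where(net.degree > 0, net.degree, 1).astype(float)
    W = net.adjacency.astype(float)
    # W D^{-1}: scale column j by 1/deg[j]
    WDinv = W @ sp.diags(1.0 / deg)
    return (sp.identity(p, format="csr") - d * WDinv).tocsr()


def _check_expression(net: GeneNetwork, e: np.ndarray) -> np.ndarray:
    e = np.asarray(e, dtype=float).ravel()
    if e.shape[0] != net.n_genes:
        raise ValueError(
            f"expression length {e.shape[0]} does not match {net.n_genes} genes"
        )
    bad = ~np.isfinite(e)
    if bad.any():
        names = [net.genes[k] for k in np.flatnonzero(bad)[:5]]
        raise ValueError(f"non-finite expression value(s) for gene(s): {names}")
    return e


def generank_sample(
    net: GeneNetwork,
    expression: np.ndarray,
    d: float = 0.5,
    solver_tol: float = 1e-8,
    shift_nonnegative: bool = False,
) -> np.ndarray:
    """Solve ``(I - d W D~^{-1}) r = (1-d) e`` for one sample.

    Parameters
    ----------
    net
        Interaction network aligned to the expression vector's gene axis.
    expression
        Length-``p`` finite expression vector for one sample.
    d
        Damping in [0, 1); default 0.5.
    solver_tol
        Residual contract: the returned ``r`` satisfies
        ``||(I - dWD~^-1) r - (1-d) e||_inf <= solver_tol * max(1, ||e||_inf)``.
    shift_nonnegative
        Subtract the vector minimum first when it is negative (the original
        GeneRank formulation assumes nonnegative input; off by default).
    """
    e = _check_expression(net, expression)
    if shift_nonnegative and e.size and e.min() < 0:
        e = e - e.min()
    A = system_matrix(net, d)
    r = _solve(A, (1.0 - d) * e[:, None], solver_tol).ravel()
    return r


def _solve(A: sp.csr_matrix, B: np.ndarray, tol: float) -> np.ndarray:
    """Solve A X = B column-wise with a residual guarantee."""
    p = A.shape[0]
    if p <= _DENSE_CUTOFF:
        X = np.linalg.solve(A.toarray(), B)
    else:
        lu = spla.splu(A.tocsc())
        X = np.column_stack([lu.solve(B[:, j]) for j in range(B.shape[1])])
    resid = np.abs(A @ X - B).max(axis=0)
    scale = np.maximum(1.0, np.abs(B).max(axis=0))
    if np.any(resid > tol * scale):
        # one refinement pass; direct factorisations rarely need more
        corr = (
            np.linalg.solve(A.toarray(), B - A @ X)
            if p <= _DENSE_CUTOFF
            else np.column_stack(
                [spla.splu(A.tocsc()).solve((B - A @ X)[:, j]) for j in range(B.shape[1])]
            )
        )
        X = X + corr
        resid = np.abs(A @ X - B).max(axis=0)
        if np.any(resid > tol * scale):
            raise ArithmeticError(
                f"solver residual {resid.max():.3e} exceeds tolerance {tol:.1e}"
            )
    return X


def generank_matrix(
    net: GeneNetwork,
    expr,
    d: float = 0.5,
    solver_tol: float = 1e-8,
    rank_transform: bool = False,
    shift_nonnegative: bool = False,
) -> GeneRankMatrix:
    """GeneRank every sample of an expression matrix against one network.

    The network's gene axis must equal the matrix's gene axis (use
    :func:`monoseq.network.align_to_genes` first).  All columns share the
    factorised system matrix, so the per-sample cost after the first solve
    is a pair of triangular solves.

    With ``rank_transform`` each output column is replaced by its
    within-sample ranks (average ranks on ties), an optional reading of
    "GeneRanks" as literal rankings rather than the solved scores.
    """
    if list(expr.genes) != list(net.genes):
        raise ValueError(
            "expression matrix gene axis does not match network gene axis; "
            "align the network with align_to_genes() first"
        )
    E = np.asarray(expr.values, dtype=float)
    if E.ndim != 2 or E.shape[1] < 1:
        raise ValueError("expression matrix must have at least one sample")
    for j in range(E.shape[1]):
        _check_expression(net, E[:, j])
    if shift_nonnegative:
        mins = E.min(axis=0)
        E = E - np.minimum(mins, 0.0)[None, :]
    A = system_matrix(net, d)
    R = _solve(A, (1.0 - d) * E, solver_tol)
    if rank_transform:
        from scipy.stats import rankdata

        R = np.column_stack([rankdata(R[:, j]) for j in range(R.shape[1])])
    return GeneRankMatrix(list(expr.genes), list(expr.samples), R, d)
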