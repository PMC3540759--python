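"""Assemble partial-correlation networks from neighborhood regressions.

Under a Gaussian graphical model the conditional dependence between genes i
and j, given all other genes, is measured by the partial correlation
rho_ij.  From the two neighborhood regression coefficients beta_ij (gene j
predicting gene i) and beta_ji it is estimated as

    rho_hat_ij = sign(beta_hat_ij) * sqrt(beta_hat_ij * beta_hat_ji)

when the two coefficients are both non-zero with the same sign, and 0
otherwise (the "AND" rule: an edge requires support in both directions and
sign agreement; the raw formula is undefined when the product is negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix
from .penalties import PenaltySpec
from .solver import NeighborhoodFit, SolverOptions, fit_neighborhood

__all__ = [
    "PartialCorrelationMatrix",
    "EdgeList",
    "estimate_network",
    "combine_neighborhoods",
    "true_partial_correlations",
    "to_edges",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    """Symmetric p x p matrix of (estimated or true) partial correlations.

    Diagonal is fixed at 1 by convention and never enters edge logic.
    ``n_clamped`` counts off-diagonal magnitudes that exceeded 1 in finite
    samples and were clamped to +/-1.
    """

    rho: np.ndarray
    gene_ids: list[str]
    n_clamped: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"rho must be square, got shape {r.shape}")
        if not np.array_equal(r, r.T):
            raise ValueError("rho must be exactly symmetric")
        if len(self.gene_ids) != r.shape[0]:
            raise ValueError("gene_ids length does not match rho")
        object.__setattr__(self, "rho", r)
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])

    @property
    def p(self) -> int:
        return self.rho.shape[0]

    def support(self, zero_tol: float = 0.0) -> np.ndarray:
        """Boolean edge-support matrix (symmetric, False diagonal)."""
        s = np.abs(self.rho) > zero_tol
        np.fill_diagonal(s, False)
        return s


@dataclass(frozen=True)
class EdgeList:
    """Undirected edges (gene_a, gene_b, rho) with per-gene degrees.

    Edges are stored with gene_a < gene_b lexicographically and sorted by
    |rho| descending (ties by gene pair) for deterministic output.
    """

    edges: list[tuple[str, str, float]]
    degree: dict[str, int]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def combine_neighborhoods(
    fits: list[NeighborhoodFit], gene_ids: list[str] | None = None
) -> PartialCorrelationMatrix:
    """Build the symmetric rho matrix from one fit per gene.

    The pairwise rule: rho_ij = sign(beta_ij) * sqrt(beta_ij * beta_ji) when
    beta_ij * beta_ji > 0, else 0.  Finite-sample magnitudes above 1 are
    clamped to 1 with a logged count.
    """
    p = len(fits)
    if p < 2:
        raise ValueError("need fits for at least 2 genes")
    order = sorted(range(p), key=lambda i: fits[i].response_index)
    fits = [fits[i] for i in order]
    if [f.response_index for f in fits] != list(range(p)):
        raise ValueError("need exactly one fit per gene 0..p-1")
    B = np.zeros((p, p))
    for f in fits:
        for k, b in f.coef.items():
            B[f.response_index, k] = b  # beta_ik: gene k predicting gene i
    prod = B * B.T
    rho = np.where(prod > 0.0, np.sign(B) * np.sqrt(np.abs(prod)), 0.0)
    n_clamped = int(np.count_nonzero(np.abs(rho) > 1.0))
    if n_clamped:
        logger.warning("clamped %d partial correlation(s) with |rho| > 1", n_clamped)
        rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0  # exact symmetry (prod symmetric already)
    np.fill_diagonal(rho, 1.0)
    gids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(p)]
    return PartialCorrelationMatrix(rho, list(gids), n_clamped)


def estimate_network(
    X, spec: PenaltySpec, opts: SolverOptions | None = None
) -> PartialCorrelationMatrix:
    """Estimate the sparse partial-correlation matrix at a fixed penalty.

    Runs one penalized neighborhood regression per gene (the objective is
    separable across response genes) and combines the p coefficient vectors
    pairwise.  For data-driven per-gene penalty strength use
    :class:`lepnet.GaussianGraphicalModel` instead.
    """
    opts = opts or SolverOptions()
    if isinstance(X, ExpressionMatrix):
        gene_ids, values = X.gene_ids, X
        p = X.p
    else:
        values = np.asarray(X, dtype=float)
        p = values.shape[0]
        gene_ids = [f"g{i}" for i in range(p)]
    if p < 2:
        raise ValueError("need at least 2 genes")
    fits = [fit_neighborhood(values, i, spec, opts) for i in range(p)]
    return combine_neighborhoods(fits, gene_ids)


def true_partial_correlations(
    sigma: np.ndarray, gene_ids: list[str] | None = None
) -> PartialCorrelationMatrix:
    """Population partial correlations implied by a covariance matrix.

    Uses the precision-matrix identity rho_ij = -omega_ij /
    sqrt(omega_ii * omega_jj) with Omega = Sigma^-1.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise ValueError("sigma must be symmetric")
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(sigma)
        raise np.linalg.LinAlgError(
            f"sigma is not positive definite (condition number {cond:.3e})"
        ) from e
    ident = np.eye(sigma.shape[0])
    omega = np.linalg.solve(L.T, np.linalg.solve(L, ident))
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    p = sigma.shape[0]
    gids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(p)]
    return PartialCorrelationMatrix(rho, list(gids))


def to_edges(pcm: PartialCorrelationMatrix, zero_tol: float = 0.0) -> EdgeList:
    """Extract the undirected edge list: one edge per unordered pair with
    |rho_ij| > zero_tol.  The solver produces hard zeros, so the default
    tolerance is exact."""
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    p = pcm.p
    gids = pcm.gene_ids
    edges = []
    degree = {g: 0 for g in gids}
    for i in range(p):
        for j in range(i + 1, p):
            r = pcm.rho[i, j]
            if abs(r) > zero_tol:
                a, b = sorted((gids[i], gids[j]))
                edges.append((a, b, float(r)))
                degree[gids[i]] += 1
                degree[gids[j]] += 1
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return EdgeList(edges, degree)
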