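"""Penalized neighborhood regression by cyclic coordinate descent.

Each gene i is regressed on all other genes (no intercept; everything is
mean-centered first) under a sparsity penalty:

    min_beta  sum_j ( X_ij - sum_{k != i} beta_k X_kj )^2
              + sum_{k != i} p_lambda(beta_k)

The solver is cyclic coordinate descent with the exact univariate threshold
operator of the chosen penalty family, so thresholded coefficients are hard
zeros.  For the nonconvex families (LEP, SCAD) each lambda is initialized
from the lasso solution at the same lambda (and, along a path, additionally
from the previous lambda's solution), which guarantees a stationary point
whose objective does not exceed the warm start's.

Predictors are standardized to unit variance before penalization by default
and coefficients are returned on the original scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _cd
from .data import ExpressionMatrix
from .penalties import PenaltySpec

__all__ = ["SolverOptions", "NeighborhoodFit", "fit_neighborhood", "regularization_path"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverOptions:
    """Coordinate-descent settings.

    ``tol`` is the maximum absolute coefficient change (standardized scale)
    allowed in the final sweep.  ``init`` controls nonconvex initialization:
    ``"lasso_warm"`` (default) starts from the lasso solution at the same
    lambda, ``"zeros"`` starts cold.  ``seed`` is reserved for randomized
    restarts and unused by the deterministic default solver.
    """

    max_iter: int = 1000
    tol: float = 1e-6
    standardize: bool = True
    init: str = "lasso_warm"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.init not in ("zeros", "lasso_warm"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class NeighborhoodFit:
    """Result of one penalized neighborhood regression.

    ``coef`` maps predictor gene index k (k != response_index) to the
    estimated coefficient beta_ki on the original data scale; ``ssr`` is the
    sum of squared residuals of the fit and ``df`` the number of exactly
    non-zero coefficients.
    """

    response_index: int
    coef: dict[int, float]
    ssr: float
    df: int
    spec: PenaltySpec
    converged: bool
    n_iter: int

    def coef_array(self, p: int) -> np.ndarray:
        """Dense length-p coefficient vector (0 at the response position)."""
        out = np.zeros(p)
        for k, b in self.coef.items():
            out[k] = b
        return out


def _as_values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    v = np.asarray(X, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError(f"expected a p x n matrix with p, n >= 2, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in expression matrix")
    return v


def _design(values: np.ndarray, i: int, standardize: bool):
    """Centered response and centered/scaled predictor design for gene i.

    Returns (y, D, colss, scales, pred_idx) where D is (n, p-1) with
    predictor columns in pred_idx order and scales holds the per-column
    standard deviations used (1.0 where standardize is off or sd == 0).
    """
    p, n = values.shape
    if not 0 <= i < p:
        raise IndexError(f"gene index {i} out of range for p={p}")
    y = values[i] - values[i].mean()
    pred_idx = np.array([k for k in range(p) if k != i])
    raw = values[pred_idx].T
    D = raw - raw.mean(axis=0)
    sd = np.sqrt((D**2).mean(axis=0))
    scales = np.ones(len(pred_idx))
    # relative guard: centering a constant column leaves ~eps*|mean| residue
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(raw).max(axis=0))
    D[:, zero_var] = 0.0
    if zero_var.any():
        logger.warning(
            "constant predictor gene(s) %s in neighborhood of gene %d; "
            "their coefficients are fixed at 0",
            pred_idx[zero_var].tolist(),
            i,
        )
    if standardize:
        nz = ~zero_var
        D[:, nz] /= sd[nz]
        scales[nz] = sd[nz]
    colss = (D**2).sum(axis=0)
    return y, np.ascontiguousarray(D), colss, scales, pred_idx


def _run_path(values, i, lambdas, family_code, kappa, alpha, opts):
    y, D, colss, scales, pred_idx = _design(values, i, opts.standardize)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs, ssrs, iters, convs = _cd.cd_path(
        D,
        y,
        colss,
        lambdas,
        family_code,
        kappa,
        alpha,
        opts.max_iter,
        opts.tol,
        opts.init == "zeros",
    )
    coefs = coefs / scales  # back to original predictor scale
    return coefs, ssrs, iters, convs, pred_idx


def fit_neighborhood(
    X, i: int, spec: PenaltySpec, opts: SolverOptions | None = None
) -> NeighborhoodFit:
    """Fit gene ``i``'s penalized neighborhood regression.

    Parameters
    ----------
    X : ExpressionMatrix or (p, n) array
        Expression data, genes in rows.
    i : int
        Index of the response gene.
    spec : PenaltySpec
        Penalty family and parameters.
    opts : SolverOptions, optional

    Returns
    -------
    NeighborhoodFit
        Coefficients (exact zeros where thresholded), SSR and df.
    """
    opts = opts or SolverOptions()
    values = _as_values(X)
    kappa, alpha = spec._kernel_params()
    coefs, ssrs, iters, convs, pred_idx = _run_path(
        values, i, [spec.lam], spec.code, kappa, alpha, opts
    )
    b = coefs[0]
    if not convs[0]:
        warnings.warn(
            f"neighborhood fit for gene {i} did not converge in "
            f"{opts.max_iter} sweeps (family={spec.family}, lam={spec.lam})",
            RuntimeWarning,
            stacklevel=2,
        )
    return NeighborhoodFit(
        response_index=int(i),
        coef={int(k): float(v) for k, v in zip(pred_idx, b) if v != 0.0},
        ssr=float(ssrs[0]),
        df=int(np.count_nonzero(b)),
        spec=spec,
        converged=bool(convs[0]),
        n_iter=int(iters[0]),
    )


def regularization_path(
    X,
    i: int,
    family: str,
    lambdas,
    fixed_params: dict | None = None,
    opts: SolverOptions | None = None,
) -> list[NeighborhoodFit]:
    """Fit gene ``i``'s neighborhood along a decreasing lambda path.

    Each solution warm-starts the next.  ``fixed_params`` carries the shape
    parameters held constant along the path (``kappa`` for LEP, ``alpha``
    for SCAD).
    """
    opts = opts or SolverOptions()
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda path")
    if lambdas.size > 1 and not np.all(np.diff(lambdas) < 0):
        raise ValueError("lambdas must be strictly decreasing")
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be >= 0")
    fixed_params = fixed_params or {}
    specs = [PenaltySpec(family, float(l), **fixed_params) for l in lambdas]
    values = _as_values(X)
    kappa, alpha = specs[0]._kernel_params()
    coefs, ssrs, iters, convs, pred_idx = _run_path(
        values, i, lambdas, specs[0].code, kappa, alpha, opts
    )
    fits = []
    for li, spec in enumerate(specs):
        b = coefs[li]
        fits.append(
            NeighborhoodFit(
                response_index=int(i),
                coef={int(k): float(v) for k, v in zip(pred_idx, b) if v != 0.0},
                ssr=float(ssrs[li]),
                df=int(np.count_nonzero(b)),
                spec=spec,
                converged=bool(convs[li]),
                n_iter=int(iters[li]),
            )
        )
    return fits
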