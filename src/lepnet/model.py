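"""Model / Results interface for sparse partial-correlation estimation.

`GaussianGraphicalModel` wraps an expression matrix; its :meth:`fit` runs
one penalized neighborhood regression per gene (LEP, SCAD or lasso; lambda
either fixed or EBIC-selected per gene), combines the coefficient pairs
into the symmetric partial-correlation matrix, and returns a
:class:`GGMResults` carrying the estimates, the per-gene fits and
selection diagnostics, and a printable summary.

Example
-------
>>> import numpy as np
>>> from lepnet import GaussianGraphicalModel, simulate
>>> truth = simulate.gen_sigma_expdecay(p=8, seed=3)
>>> X = simulate.sample_mvn(truth, n=500, seed=4)
>>> res = GaussianGraphicalModel(X).fit(penalty="lep")
>>> res.edges().n_edges  # doctest: +SKIP
7
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .network import (
    EdgeList,
    PartialCorrelationMatrix,
    combine_neighborhoods,
    to_edges,
)
from .penalties import PenaltySpec
from .solver import SolverOptions, fit_neighborhood, regularization_path
from .tuning import TuningConfig, ebic_score, lambda_grid, lambda_max_lasso, select_lambda

__all__ = ["GaussianGraphicalModel", "GGMResults"]


class GaussianGraphicalModel:
    """Gaussian graphical model over a gene-by-sample expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame or (p, n) array
        Genes in rows, samples in columns.  Values are assumed continuous
        (typically log-scale expression).
    """

    def __init__(self, data, gene_ids=None, sample_ids=None):
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ExpressionMatrix.from_dataframe(data)
        else:
            self.data = ExpressionMatrix(np.asarray(data, dtype=float), gene_ids, sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GaussianGraphicalModel":
        return cls(ExpressionMatrix.from_dataframe(df))

    @classmethod
    def from_tsv(cls, path) -> "GaussianGraphicalModel":
        from .io import read_expression_tsv

        return cls(read_expression_tsv(path))

    @property
    def p(self) -> int:
        return self.data.p

    @property
    def n(self) -> int:
        return self.data.n

    def fit(
        self,
        penalty: str = "lep",
        lam: float | None = None,
        tuning: TuningConfig | None = None,
        solver: SolverOptions | None = None,
        global_lambda: bool = False,
    ) -> "GGMResults":
        """Estimate the sparse partial-correlation network.

        Parameters
        ----------
        penalty : {"lep", "lasso", "scad"}
            Penalty family.
        lam : float, optional
            Fixed penalty strength applied to every neighborhood.  When
            omitted (default), lambda is selected by EBIC -- per gene by
            default, or one shared lambda minimizing the summed EBIC when
            ``global_lambda`` is set.
        tuning : TuningConfig, optional
            EBIC settings (gamma, fixed kappa / alpha, lambda grid).
        solver : SolverOptions, optional

        Returns
        -------
        GGMResults
        """
        tuning = tuning or TuningConfig()
        solver = solver or SolverOptions()
        X = self.data
        if lam is not None:
            spec = PenaltySpec(penalty, float(lam), **tuning.fixed_params(penalty))
            fits = [fit_neighborhood(X, i, spec, solver) for i in range(X.p)]
            lambdas = [float(lam)] * X.p
            scores = None
        elif global_lambda:
            fits, lambdas, scores = self._fit_global_lambda(penalty, tuning, solver)
        else:
            fits, lambdas, scores = [], [], []
            for i in range(X.p):
                best_fit, best_lam, path_scores = select_lambda(
                    X, i, penalty, tuning, solver
                )
                fits.append(best_fit)
                lambdas.append(best_lam)
                scores.append(path_scores)
        pcm = combine_neighborhoods(fits, X.gene_ids)
        return GGMResults(
            model=self,
            penalty=penalty,
            partial_correlations=pcm,
            neighborhood_fits=fits,
            selected_lambdas=list(lambdas),
            tuning=tuning,
            path_scores=scores,
        )

    def _fit_global_lambda(self, penalty, tuning, solver):
        """One shared lambda minimizing the EBIC summed across genes."""
        X = self.data
        if tuning.lambda_grid is not None:
            grid = np.asarray(tuning.lambda_grid)
        else:
            lam_max = max(
                lambda_max_lasso(X, i, solver.standardize) for i in range(X.p)
            )
            grid = lambda_grid(max(lam_max, 1e-12), tuning.n_lambda, tuning.lambda_min_ratio)
        paths = [
            regularization_path(
                X, i, penalty, grid, tuning.fixed_params(penalty), solver
            )
            for i in range(X.p)
        ]
        totals = np.zeros(len(grid))
        for path in paths:
            for li, fit in enumerate(path):
                totals[li] += ebic_score(fit, X.n, X.p, tuning.gamma)
        finite = np.isfinite(totals)
        if not finite.any():
            raise RuntimeError("all global-lambda fits degenerate (non-finite EBIC)")
        best = int(np.flatnonzero(finite)[np.argmin(totals[finite])])
        fits = [path[best] for path in paths]
        scores = [
            [(float(grid[li]), float(totals[li]), sum(p[li].df for p in paths))
             for li in range(len(grid))]
        ]
        return fits, [float(grid[best])] * X.p, scores


@dataclass(frozen=True)
class GGMResults:
    """Fitted sparse partial-correlation network.

    Attributes
    ----------
    partial_correlations : PartialCorrelationMatrix
        The symmetric rho-hat matrix (diagonal 1).
    neighborhood_fits : list of NeighborhoodFit
        One penalized regression per gene.
    selected_lambdas : list of float
        Per-gene penalty strengths actually used.
    """

    model: GaussianGraphicalModel
    penalty: str
    partial_correlations: PartialCorrelationMatrix
    neighborhood_fits: list
    selected_lambdas: list
    tuning: TuningConfig
    path_scores: list | None = None

    @property
    def rho(self) -> np.ndarray:
        return self.partial_correlations.rho

    @property
    def gene_ids(self) -> list:
        return self.partial_correlations.gene_ids

    def rho_frame(self) -> pd.DataFrame:
        g = self.gene_ids
        return pd.DataFrame(self.rho, index=g, columns=g)

    def support(self, zero_tol: float = 0.0) -> np.ndarray:
        return self.partial_correlations.support(zero_tol)

    def edges(self, zero_tol: float = 0.0) -> EdgeList:
        return to_edges(self.partial_correlations, zero_tol)

    def degree(self) -> pd.Series:
        d = self.edges().degree
        return pd.Series([d[g] for g in self.gene_ids], index=self.gene_ids, name="degree")

    def summary(self) -> str:
        """Human-readable fit summary (printable)."""
        el = self.edges()
        lines = []
        lines.append("Gaussian graphical model (penalized neighborhood regression)")
        lines.append("=" * 62)
        lines.append(f"penalty family:        {self.penalty}")
        if self.penalty == "lep":
            lines.append(f"kappa (fixed):         {self.tuning.kappa_fixed}")
        if self.penalty == "scad":
            lines.append(f"alpha (fixed):         {self.tuning.alpha_fixed}")
        lines.append(f"genes (p):             {self.model.p}")
        lines.append(f"samples (n):           {self.model.n}")
        lines.append(f"edges identified:      {el.n_edges}")
        lines.append(f"EBIC gamma:            {self.tuning.gamma}")
        clamped = self.partial_correlations.n_clamped
        if clamped:
            lines.append(f"|rho| clamped to 1:    {clamped}")
        lines.append("-" * 62)
        lines.append(f"{'gene':<16}{'lambda':>12}{'df':>6}{'ssr':>14}{'degree':>8}")
        deg = el.degree
        for i, g in enumerate(self.gene_ids):
            f = self.neighborhood_fits[i]
            lines.append(
                f"{g:<16}{self.selected_lambdas[i]:>12.5g}{f.df:>6d}"
                f"{f.ssr:>14.5g}{deg[g]:>8d}"
            )
        lines.append("-" * 62)
        top = el.edges[:10]
        if top:
            lines.append("strongest edges (|rho| desc):")
            for a, b, r in top:
                lines.append(f"  {a} -- {b}   rho = {r:+.4f}")
        return "\n".join(lines)
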