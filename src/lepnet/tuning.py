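"""Penalty-strength selection by the extended BIC.

The shape parameter is held fixed (kappa = 0.01 for LEP, alpha = 3.7 for
SCAD) and only lambda is tuned, per neighborhood regression, over a
geometric grid anchored at the smallest lambda that zeroes every lasso
coefficient on the standardized data.

The criterion is the Gaussian-regression extended BIC

    EBIC(fit) = n log(SSR/n) + df log(n) + 2 gamma df log(p - 1),

where p - 1 is the number of candidate predictors of a neighborhood and
gamma in [0, 1] controls the extended model-space term (gamma = 0 recovers
ordinary BIC).  Lower is better; ties are broken toward larger lambda.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .solver import NeighborhoodFit, SolverOptions, regularization_path, _design, _as_values

__all__ = ["TuningConfig", "ebic_score", "lambda_grid", "select_lambda"]


@dataclass(frozen=True)
class TuningConfig:
    """EBIC tuning settings.

    ``lambda_grid`` may be given explicitly (strictly decreasing positive
    reals); otherwise a geometric grid of ``n_lambda`` values from
    lambda_max down to ``lambda_min_ratio * lambda_max`` is built per
    neighborhood.
    """

    criterion: str = "ebic"
    gamma: float = 0.5
    kappa_fixed: float = 0.01
    alpha_fixed: float = 3.7
    lambda_grid: tuple | None = None
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.criterion != "ebic":
            raise ValueError(f"unsupported criterion {self.criterion!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not self.kappa_fixed > 0:
            raise ValueError("kappa_fixed must be > 0")
        if not self.alpha_fixed > 2:
            raise ValueError("alpha_fixed must be > 2")
        if self.lambda_grid is not None:
            g = tuple(float(x) for x in self.lambda_grid)
            if len(g) == 0:
                raise ValueError("empty lambda grid")
            if any(x <= 0 for x in g):
                raise ValueError("lambda grid values must be > 0")
            if len(g) > 1 and not all(a > b for a, b in zip(g, g[1:])):
                raise ValueError("lambda grid must be strictly decreasing")
            object.__setattr__(self, "lambda_grid", g)
        else:
            if self.n_lambda < 1:
                raise ValueError("n_lambda must be >= 1")
            if not 0 < self.lambda_min_ratio < 1:
                raise ValueError("lambda_min_ratio must be in (0, 1)")

    def fixed_params(self, family: str) -> dict:
        if family == "lep":
            return {"kappa": self.kappa_fixed}
        if family == "scad":
            return {"alpha": self.alpha_fixed}
        return {}


def ebic_score(fit: NeighborhoodFit, n: int, p: int, gamma: float) -> float:
    """Extended BIC of one neighborhood fit (lower is better).

    A perfect fit (SSR = 0) returns ``-inf`` with a warning so it is
    flagged rather than silently winning the selection.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples for EBIC")
    if fit.ssr <= 0.0:
        warnings.warn(
            f"SSR = 0 in neighborhood of gene {fit.response_index} "
            "(perfect fit); EBIC is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return -math.inf
    return (
        n * math.log(fit.ssr / n)
        + fit.df * math.log(n)
        + 2.0 * gamma * fit.df * math.log(p - 1)
    )


def lambda_max_lasso(X, i: int, standardize: bool = True) -> float:
    """Smallest lambda at which the lasso neighborhood of gene i is
    all-zero on the standardized data: 2 * max_k |x_k . y|."""
    values = _as_values(X)
    y, D, colss, _, _ = _design(values, i, standardize)
    return float(2.0 * np.max(np.abs(D.T @ y)))


def lambda_grid(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    """Geometric grid from lam_max down to min_ratio * lam_max."""
    if not lam_max > 0:
        raise ValueError("lambda_max must be > 0")
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.power(min_ratio, np.linspace(0.0, 1.0, n_lambda))


def select_lambda(
    X,
    i: int,
    spec_family: str,
    cfg: TuningConfig | None = None,
    opts: SolverOptions | None = None,
):
    """EBIC-select lambda for gene i's neighborhood.

    Fits the regularization path, scores every fit, and returns
    ``(best_fit, best_lambda, path_scores)`` where ``path_scores`` is the
    list of ``(lambda, ebic, df)`` along the path in decreasing-lambda
    order.  Exact score ties are broken toward larger lambda (the sparser
    model, encountered first on the path).
    """
    cfg = cfg or TuningConfig()
    opts = opts or SolverOptions()
    values = _as_values(X)
    p, n = values.shape
    if cfg.lambda_grid is not None:
        grid = np.asarray(cfg.lambda_grid)
    else:
        lam_max = lambda_max_lasso(values, i, opts.standardize)
        if lam_max <= 0.0:  # constant response: any lambda gives the null fit
            lam_max = 1.0
        grid = lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)
    fits = regularization_path(
        values, i, spec_family, grid, cfg.fixed_params(spec_family), opts
    )
    best_fit, best_lam, best_score = None, None, math.inf
    path_scores = []
    for lam, fit in zip(grid, fits):
        score = ebic_score(fit, n, p, cfg.gamma)
        path_scores.append((float(lam), score, fit.df))
        # non-finite scores are flagged degenerate and never selected
        if math.isfinite(score) and score < best_score:
            best_fit, best_lam, best_score = fit, float(lam), score
    if best_fit is None:
        raise RuntimeError(
            f"all {len(path_scores)} path fits degenerate (non-finite EBIC) "
            f"for gene {i}"
        )
    return best_fit, best_lam, path_scores
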