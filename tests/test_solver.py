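"""Coordinate-descent neighborhood solver against independent oracles."""

import numpy as np
import pytest

from lepnet.penalties import PenaltySpec, penalty_value
from lepnet.solver import SolverOptions, fit_neighborhood, regularization_path


def neighborhood_objective(X, i, coef, spec, standardize=True):
    """Objective on the standardized design, computed independently."""
    values = np.asarray(getattr(X, "values", X), dtype=float)
    y = values[i] - values[i].mean()
    pred = [k for k in range(values.shape[0]) if k != i]
    D = values[pred].T - values[pred].mean(axis=1)
    sd = np.sqrt((D**2).mean(axis=0))
    if standardize:
        D = D / sd
    b_std = np.array([coef.get(k, 0.0) for k in pred])
    if standardize:
        b_std = b_std * sd  # original-scale coef -> standardized coef
    r = y - D @ b_std
    return float(r @ r + penalty_value(b_std, spec).sum())


def grid_oracle_objective(X, i, spec, step=0.01, lim=2.0):
    """Brute-force minimum of the standardized objective over a full
    (p-1)-dimensional grid."""
    values = np.asarray(X, dtype=float)
    y = values[i] - values[i].mean()
    pred = [k for k in range(values.shape[0]) if k != i]
    D = values[pred].T - values[pred].mean(axis=1)
    sd = np.sqrt((D**2).mean(axis=0))
    D = D / sd
    m = len(pred)
    axis = np.arange(-lim, lim + step / 2, step)
    G = D.T @ D
    c = D.T @ y
    yty = float(y @ y)
    if m == 2:
        B1, B2 = np.meshgrid(axis, axis, indexing="ij")
        obj = (
            yty
            - 2 * (c[0] * B1 + c[1] * B2)
            + G[0, 0] * B1**2
            + G[1, 1] * B2**2
            + 2 * G[0, 1] * B1 * B2
            + penalty_value(B1, spec)
            + penalty_value(B2, spec)
        )
        return float(obj.min())
    if m == 3:
        best = np.inf
        B2, B3 = np.meshgrid(axis, axis, indexing="ij")
        base23 = (
            G[1, 1] * B2**2
            + G[2, 2] * B3**2
            + 2 * G[1, 2] * B2 * B3
            - 2 * (c[1] * B2 + c[2] * B3)
            + penalty_value(B2, spec)
            + penalty_value(B3, spec)
        )
        for b1 in axis:
            obj = (
                yty
                + G[0, 0] * b1**2
                - 2 * c[0] * b1
                + 2 * b1 * (G[0, 1] * B2 + G[0, 2] * B3)
                + base23
                + penalty_value(b1, spec)
            )
            best = min(best, float(obj.min()))
        return best
    raise NotImplementedError(m)


def random_spec(rng, family):
    lam = rng.uniform(0.5, 20.0)
    if family == "lep":
        return PenaltySpec(family, lam, kappa=0.01)
    if family == "scad":
        return PenaltySpec(family, lam, alpha=3.7)
    return PenaltySpec(family, lam)


class TestUnpenalizedLimit:
    def test_lambda_zero_recovers_ols_all_families(self, rng):
        X = rng.standard_normal((4, 60))
        X[1] = 0.8 * X[0] + 0.05 * rng.standard_normal(60)
        y = X[1] - X[1].mean()
        pred = [0, 2, 3]
        D = (X[pred].T - X[pred].mean(axis=1))
        b_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        for fam, kw in (("lasso", {}), ("lep", {"kappa": 0.01}), ("scad", {})):
            fit = fit_neighborhood(X, 1, PenaltySpec(fam, 0.0, **kw))
            b = fit.coef_array(4)[pred]
            np.testing.assert_allclose(b, b_ols, atol=1e-6)
        assert abs(b_ols[0] - 0.8) < 0.05

    def test_total_shrinkage_limit(self, rng):
        X = rng.standard_normal((3, 20))
        fit = fit_neighborhood(X, 0, PenaltySpec("lep", 1e6, kappa=0.01))
        assert fit.coef == {}
        assert fit.df == 0
        y = X[0] - X[0].mean()
        assert fit.ssr == pytest.approx(float(y @ y), rel=1e-10)


class TestGridOracle:
    @pytest.mark.parametrize("family", ["lasso", "lep", "scad"])
    def test_objective_not_worse_than_brute_force(self, family):
        """CD reaches an objective value at least as low as a 0.01-step
        exhaustive grid search, up to the grid's own resolution."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            X = rng.standard_normal((3, 20))
            spec = random_spec(rng, family)
            fit = fit_neighborhood(X, 0, spec)
            f_cd = neighborhood_objective(X, 0, fit.coef, spec)
            f_grid = grid_oracle_objective(X, 0, spec)
            # slack: one grid step of curvature + penalty Lipschitz bound
            slack = 0.05 + 0.01 * spec.lam / (0.01 if family == "lep" else 1.0) * 0.01
            assert f_cd <= f_grid + slack


class TestAgainstSklearnLasso:
    def test_coefficients_match_reference_cd(self):
        """Lasso coefficients agree with scikit-learn's independent
        soft-threshold coordinate descent to 1e-5."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(7)
        for _ in range(10):
            n, p = 50, 10
            X = rng.standard_normal((p, n))
            lam = rng.uniform(1.0, 30.0)
            fit = fit_neighborhood(
                X, 0, PenaltySpec("lasso", lam), SolverOptions(tol=1e-10, max_iter=5000)
            )
            y = X[0] - X[0].mean()
            D = (X[1:].T - X[1:].mean(axis=1))
            sd = np.sqrt((D**2).mean(axis=0))
            Ds = D / sd
            # our objective ||y-Db||^2 + lam|b| == 2n*( (1/2n)||.||^2 + (lam/2n)|b| )
            ref = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=1e-12, max_iter=100000)
            ref.fit(Ds, y)
            b_ref = ref.coef_ / sd
            b_ours = fit.coef_array(p)[1:]
            np.testing.assert_allclose(b_ours, b_ref, atol=1e-5)


class TestPath:
    def test_endpoints(self, small_gauss):
        X = small_gauss
        fits = regularization_path(X, 0, "lasso", [1e6, 0.0])
        assert fits[0].df == 0
        y = X[0] - X[0].mean()
        D = (X[1:].T - X[1:].mean(axis=1))
        b_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        np.testing.assert_allclose(fits[1].coef_array(5)[1:], b_ols, atol=1e-5)

    def test_single_lambda_equals_fit_neighborhood(self, chain_data):
        _, X = chain_data
        for fam, fp in (("lasso", {}), ("lep", {"kappa": 0.01}), ("scad", {"alpha": 3.7})):
            one = regularization_path(X, 2, fam, [3.0], fp)[0]
            single = fit_neighborhood(X, 2, PenaltySpec(fam, 3.0, **fp))
            assert one.coef.keys() == single.coef.keys()
            for k in one.coef:
                assert one.coef[k] == pytest.approx(single.coef[k], abs=1e-8)

    def test_lasso_df_monotone_along_path(self):
        rng = np.random.default_rng(11)
        truth_cov = np.eye(5)
        for i in range(5):
            for j in range(5):
                truth_cov[i, j] = 0.6 ** abs(i - j)
        L = np.linalg.cholesky(truth_cov)
        X = L @ rng.standard_normal((5, 120))
        lambdas = np.geomspace(200, 0.2, 20)
        fits = regularization_path(X, 0, "lasso", lambdas)
        dfs = [f.df for f in fits]
        assert all(a <= b for a, b in zip(dfs, dfs[1:]))

    def test_input_validation(self, small_gauss):
        with pytest.raises(ValueError, match="empty"):
            regularization_path(small_gauss, 0, "lasso", [])
        with pytest.raises(ValueError, match="decreasing"):
            regularization_path(small_gauss, 0, "lasso", [1.0, 2.0])


class TestInvariances:
    def test_permutation_of_predictors(self, rng):
        """Convex (lasso) solutions are invariant under predictor order."""
        X = rng.standard_normal((6, 50))
        spec = PenaltySpec("lasso", 5.0)
        fit = fit_neighborhood(X, 0, spec, SolverOptions(tol=1e-10))
        perm = [0, 4, 2, 5, 1, 3]  # response stays at 0
        Xp = X[perm]
        fitp = fit_neighborhood(Xp, 0, spec, SolverOptions(tol=1e-10))
        inv = {pi: k for k, pi in enumerate(perm)}
        for k, v in fit.coef.items():
            assert fitp.coef.get(inv[k], 0.0) == pytest.approx(v, abs=1e-6)

    def test_nonconvex_objective_not_above_lasso_warm_start(self, chain_data):
        _, X = chain_data
        for fam, fp in (("lep", {"kappa": 0.01}), ("scad", {"alpha": 3.7})):
            spec = PenaltySpec(fam, 4.0, **fp)
            fit = fit_neighborhood(X, 3, spec)
            lasso_fit = fit_neighborhood(X, 3, PenaltySpec("lasso", 4.0))
            f_n = neighborhood_objective(X, 3, fit.coef, spec)
            f_l = neighborhood_objective(X, 3, lasso_fit.coef, spec)
            assert f_n <= f_l + 1e-9

    def test_zero_init_reaches_stationary_fit(self, chain_data):
        _, X = chain_data
        spec = PenaltySpec("lep", 4.0, kappa=0.01)
        fit = fit_neighborhood(X, 3, spec, SolverOptions(init="zeros"))
        assert fit.converged


class TestDegenerateInputs:
    def test_constant_predictor_coefficient_zero(self, rng, caplog):
        X = rng.standard_normal((4, 30))
        X[2] = 1.7  # constant gene
        import logging

        with caplog.at_level(logging.WARNING, logger="lepnet.solver"):
            fit = fit_neighborhood(X, 0, PenaltySpec("lasso", 1.0))
        assert 2 not in fit.coef
        assert "constant predictor" in caplog.text

    def test_constant_response_all_zero_fit(self, rng):
        X = rng.standard_normal((4, 30))
        X[0] = 3.14
        fit = fit_neighborhood(X, 0, PenaltySpec("lasso", 1.0))
        assert fit.df == 0
        assert fit.ssr == pytest.approx(0.0, abs=1e-20)

    def test_non_finite_rejected(self):
        X = np.ones((3, 10))
        X[0] = np.linspace(0, 1, 10)
        X[1, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_neighborhood(X, 0, PenaltySpec("lasso", 1.0))
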