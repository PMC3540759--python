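"""Penalty values, derivatives, and the exact scalar threshold operator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lepnet.penalties import PenaltySpec, penalty_derivative, penalty_value, scalar_threshold


def _random_spec(rng):
    fam = rng.choice(["lasso", "lep", "scad"])
    lam = rng.uniform(0.01, 5.0)
    if fam == "lep":
        return PenaltySpec(fam, lam, kappa=rng.uniform(0.005, 2.0))
    if fam == "scad":
        return PenaltySpec(fam, lam, alpha=rng.uniform(2.1, 6.0))
    return PenaltySpec(fam, lam)


class TestSpecValidation:
    def test_lep_requires_kappa(self):
        with pytest.raises(ValueError, match="kappa"):
            PenaltySpec("lep", 1.0)
        with pytest.raises(ValueError, match="kappa"):
            PenaltySpec("lep", 1.0, kappa=-0.1)

    def test_scad_alpha_default_and_bound(self):
        assert PenaltySpec("scad", 1.0).alpha == 3.7
        with pytest.raises(ValueError, match="alpha"):
            PenaltySpec("scad", 1.0, alpha=2.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lam"):
            PenaltySpec("lasso", -0.5)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            PenaltySpec("ridge", 1.0)

    def test_cross_family_params_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec("lasso", 1.0, kappa=0.1)
        with pytest.raises(ValueError):
            PenaltySpec("lep", 1.0, kappa=0.1, alpha=3.0)

    def test_spec_is_immutable(self):
        spec = PenaltySpec("lasso", 1.0)
        with pytest.raises(AttributeError):
            spec.lam = 2.0


class TestPenaltyValue:
    @pytest.mark.parametrize(
        "spec",
        [
            PenaltySpec("lasso", 0.7),
            PenaltySpec("lep", 1.3, kappa=0.05),
            PenaltySpec("scad", 0.9, alpha=3.7),
        ],
        ids=["lasso", "lep", "scad"],
    )
    def test_zero_at_origin(self, spec):
        assert penalty_value(0.0, spec) == 0.0

    def test_lep_saturates_at_lambda(self):
        spec = PenaltySpec("lep", 1.0, kappa=0.01)
        assert penalty_value(1e6, spec) == pytest.approx(1.0, abs=1e-12)

    def test_lep_closed_form(self):
        spec = PenaltySpec("lep", 2.0, kappa=1.0)
        assert penalty_value(1.0, spec) == pytest.approx(2 * (1 - math.exp(-1)), rel=1e-12)

    def test_lasso_closed_form(self):
        assert penalty_value(0.3, PenaltySpec("lasso", 0.5)) == pytest.approx(0.15)

    def test_scad_continuity_at_knots(self):
        lam, a = 0.8, 3.7
        spec = PenaltySpec("scad", lam, alpha=a)
        for knot in (lam, a * lam):
            lo = penalty_value(knot - 1e-9, spec)
            hi = penalty_value(knot + 1e-9, spec)
            assert hi == pytest.approx(lo, abs=1e-7)
        # constant level beyond alpha*lam
        assert penalty_value(10 * a * lam, spec) == pytest.approx(
            0.5 * lam**2 * (a + 1), rel=1e-12
        )

    def test_even_zero_origin_monotone(self):
        rng = np.random.default_rng(1)
        betas = np.linspace(0, 8, 400)
        for _ in range(30):
            spec = _random_spec(rng)
            vals = penalty_value(betas, spec)
            assert np.all(np.diff(vals) >= -1e-12), spec
            assert np.allclose(penalty_value(-betas, spec), vals)
            assert vals[0] == 0.0


class TestPenaltyDerivative:
    def test_scad_inner_branch_is_lambda(self):
        lam = 0.9
        spec = PenaltySpec("scad", lam, alpha=3.2)
        assert penalty_derivative(0.5 * lam, spec) == pytest.approx(lam)
        assert penalty_derivative(-0.5 * lam, spec) == pytest.approx(-lam)

    def test_scad_vanishes_beyond_alpha_lambda(self):
        lam = 0.4
        spec = PenaltySpec("scad", lam, alpha=3.7)
        assert penalty_derivative(5 * lam, spec) == 0.0

    def test_lep_closed_form(self):
        kappa = 0.3
        spec = PenaltySpec("lep", 1.0, kappa=kappa)
        assert penalty_derivative(kappa, spec) == pytest.approx(
            math.exp(-1) / kappa, rel=1e-12
        )

    def test_matches_numerical_gradient(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            spec = _random_spec(rng)
            b = rng.uniform(0.05, 3.0) * rng.choice([-1, 1])
            if spec.family == "scad":
                # avoid the two spline knots where the derivative kinks
                if min(abs(abs(b) - spec.lam), abs(abs(b) - spec.alpha * spec.lam)) < 1e-3:
                    continue
            h = 1e-6
            num = (penalty_value(b + h, spec) - penalty_value(b - h, spec)) / (2 * h)
            assert penalty_derivative(b, spec) == pytest.approx(num, abs=1e-4)


class TestScalarThreshold:
    def test_lasso_soft_threshold(self):
        spec = PenaltySpec("lasso", 0.5)
        assert scalar_threshold(0.3, 1.0, spec) == 0.0
        assert scalar_threshold(2.0, 1.0, spec) == pytest.approx(1.5)
        assert scalar_threshold(-2.0, 1.0, spec) == pytest.approx(-1.5)

    def test_lep_flat_region_passes_through(self):
        # at |z| >> kappa the LEP is flat, so the minimizer is ~z itself
        spec = PenaltySpec("lep", 0.1, kappa=0.01)
        b = scalar_threshold(2.0, 1.0, spec)
        grid = np.arange(-4, 4, 1e-4)
        obj = 0.5 * (2.0 - grid) ** 2 + penalty_value(grid, spec)
        assert 0.5 * (2.0 - b) ** 2 + penalty_value(b, spec) <= obj.min() + 1e-8
        assert b == pytest.approx(2.0, abs=1e-3)

    def test_zero_input_maps_to_zero(self):
        for spec in (
            PenaltySpec("lasso", 1.0),
            PenaltySpec("lep", 1.0, kappa=0.1),
            PenaltySpec("scad", 1.0),
        ):
            assert scalar_threshold(0.0, 2.0, spec) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            scalar_threshold(float("nan"), 1.0, PenaltySpec("lasso", 1.0))

    def test_grid_search_oracle_1000_draws(self):
        """The returned point is a global minimizer: its objective is within
        1e-3 of a step-1e-4 grid search over [-2|z|, 2|z|]."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            spec = _random_spec(rng)
            z = rng.uniform(-3, 3)
            scale = rng.uniform(0.2, 50.0)
            b = scalar_threshold(z, scale, spec)
            lim = max(2 * abs(z), 0.1)
            grid = np.arange(-lim, lim, 1e-4)
            obj = 0.5 * scale * (z - grid) ** 2 + penalty_value(grid, spec)
            f_b = 0.5 * scale * (z - b) ** 2 + penalty_value(b, spec)
            assert f_b <= obj.min() + 1e-3

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        z=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        lam=st.floats(0, 10),
        fam=st.sampled_from(["lasso", "lep", "scad"]),
        shape=st.floats(0.005, 5),
    )
    def test_odd_and_shrinking(self, z, scale, lam, fam, shape):
        """threshold(-z) = -threshold(z) and |threshold(z)| <= |z| with the
        same sign (shrinkage never overshoots the least-squares solution)."""
        if fam == "lep":
            spec = PenaltySpec(fam, lam, kappa=shape)
        elif fam == "scad":
            spec = PenaltySpec(fam, lam, alpha=2.1 + shape)
        else:
            spec = PenaltySpec(fam, lam)
        b = scalar_threshold(z, scale, spec)
        assert scalar_threshold(-z, scale, spec) == pytest.approx(-b, abs=1e-12)
        assert abs(b) <= abs(z) + 1e-12
        assert b * z >= 0.0

    def test_lep_limits(self):
        # kappa -> inf: derivative at 0+ is lam/kappa (rescaled L1 near 0)
        lam, kappa = 2.0, 1e4
        spec = PenaltySpec("lep", lam, kappa=kappa)
        d = penalty_derivative(1e-6, spec)
        assert d == pytest.approx(lam / kappa, rel=1e-4)
        # fixed lam: value saturates at lam as |beta| -> inf
        spec2 = PenaltySpec("lep", lam, kappa=0.5)
        assert penalty_value(1e4, spec2) == pytest.approx(lam, rel=1e-9)
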