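"""Penalty families for sparse neighborhood regression.

Three interchangeable penalties are supported:

``lasso``
    The L1 penalty :math:`p_\\lambda(\\beta) = \\lambda|\\beta|`.
``scad``
    The smoothly clipped absolute deviation penalty, defined through its
    derivative :math:`p'_\\lambda(\\beta) = \\lambda\\{I(|\\beta|\\le\\lambda)
    + (\\alpha\\lambda-|\\beta|)_+ I(|\\beta|>\\lambda) /
    (\\lambda(\\alpha-1))\\}` with shape parameter :math:`\\alpha > 2`.
``lep``
    The Laplace error penalty
    :math:`p_\\lambda(\\beta) = \\lambda(1 - e^{-|\\beta|/\\kappa})`,
    a bounded, almost-smooth nonconvex penalty that approaches an L0
    penalty of strength :math:`\\lambda` as :math:`\\kappa \\to 0`.

Each family exposes its value, its derivative away from the origin, and the
exact global minimizer of the univariate proximal subproblem used by the
coordinate-descent solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PenaltySpec",
    "penalty_value",
    "penalty_derivative",
    "scalar_threshold",
    "FAMILY_CODES",
]

#: integer codes shared with the compiled coordinate-descent kernels
FAMILY_CODES = {"lasso": 0, "lep": 1, "scad": 2}

_DEFAULT_SCAD_ALPHA = 3.7  # conventional SCAD shape


@dataclass(frozen=True)
class PenaltySpec:
    """Immutable description of a penalty family and its parameters.

    Parameters
    ----------
    family : {"lep", "lasso", "scad"}
        Penalty family.
    lam : float
        Penalty strength lambda, >= 0.
    kappa : float, optional
        LEP shape parameter kappa > 0.  Required iff ``family == "lep"``.
    alpha : float, optional
        SCAD shape parameter alpha > 2.  Defaults to 3.7 for SCAD;
        must be absent otherwise.
    """

    family: str
    lam: float
    kappa: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_CODES:
            raise ValueError(
                f"unknown penalty family {self.family!r}; "
                f"expected one of {sorted(FAMILY_CODES)}"
            )
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")
        if self.family == "lep":
            if self.kappa is None or not self.kappa > 0:
                raise ValueError("lep requires kappa > 0")
            if self.alpha is not None:
                raise ValueError("alpha is a SCAD parameter, not a LEP one")
        elif self.family == "scad":
            if self.kappa is not None:
                raise ValueError("kappa is a LEP parameter, not a SCAD one")
            if self.alpha is None:
                object.__setattr__(self, "alpha", _DEFAULT_SCAD_ALPHA)
            if not self.alpha > 2:
                raise ValueError(f"scad requires alpha > 2, got {self.alpha}")
        else:  # lasso
            if self.kappa is not None or self.alpha is not None:
                raise ValueError("lasso takes no shape parameters")

    @property
    def code(self) -> int:
        """Integer family code used by the compiled solver kernels."""
        return FAMILY_CODES[self.family]

    def _kernel_params(self) -> tuple[float, float]:
        """(kappa, alpha) padded with harmless defaults for the kernels."""
        return (self.kappa or 1.0, self.alpha or _DEFAULT_SCAD_ALPHA)


def penalty_value(beta, spec: PenaltySpec):
    """Evaluate the penalty ``p_lambda(beta)``.

    Even in ``beta``, zero at the origin, non-decreasing in ``|beta|``.
    Accepts scalars or arrays.
    """
    b = np.abs(np.asarray(beta, dtype=float))
    lam = spec.lam
    if spec.family == "lasso":
        out = lam * b
    elif spec.family == "lep":
        out = lam * (1.0 - np.exp(-b / spec.kappa))
    else:  # scad: integral of the derivative from 0
        a = spec.alpha
        out = np.where(
            b <= lam,
            lam * b,
            np.where(
                b <= a * lam,
                # lam^2 + [a*lam*(b-lam) - (b^2-lam^2)/2] / (a-1)
                lam**2 + (a * lam * (b - lam) - 0.5 * (b**2 - lam**2)) / (a - 1.0),
                0.5 * lam**2 * (a + 1.0),
            ),
        )
    return out if out.ndim else float(out)


def penalty_derivative(beta, spec: PenaltySpec):
    """Derivative of :func:`penalty_value` with respect to ``beta``.

    At the origin the subdifferential is set-valued for every family; this
    returns 0 there (callers handle the origin through the threshold
    operator's candidate comparison, never through this derivative).
    """
    b = np.asarray(beta, dtype=float)
    ab = np.abs(b)
    sgn = np.sign(b)
    lam = spec.lam
    if spec.family == "lasso":
        out = lam * sgn
    elif spec.family == "lep":
        out = (lam / spec.kappa) * np.exp(-ab / spec.kappa) * sgn
    else:
        a = spec.alpha
        mag = np.where(
            ab <= lam,
            lam,
            np.maximum(a * lam - ab, 0.0) / (a - 1.0),
        )
        out = mag * sgn
    return out if out.ndim else float(out)


def _prox_objective(b: float, z: float, half_scale: float, spec: PenaltySpec) -> float:
    return half_scale * (z - b) ** 2 + penalty_value(b, spec)


def _lep_threshold(z: float, s: float, lam: float, kappa: float) -> float:
    """Global minimizer of s*(z-b)^2 + lam*(1-exp(-|b|/kappa)).

    For z > 0 the derivative on b > 0 is
    h(b) = 2 s (b - z) + (lam/kappa) exp(-b/kappa), which is strictly
    convex, so it has at most two roots; the larger root (the minus-to-plus
    crossing) is the only interior local minimum.  The global minimizer is
    that root or 0, decided by comparing objective values (ties go to 0).
    """
    if lam == 0.0 or z == 0.0:
        return z
    sign = 1.0 if z > 0 else -1.0
    z = abs(z)

    def h(b: float) -> float:
        return 2.0 * s * (b - z) + (lam / kappa) * math.exp(-b / kappa)

    # minimizer of the convex h; h is decreasing before m0, increasing after
    arg = lam / (2.0 * s * kappa * kappa)
    m0 = kappa * math.log(arg) if arg > 1.0 else 0.0
    if h(m0) >= 0.0:
        return 0.0
    # bracket the minus-to-plus root in [m0, hi]
    hi = max(z, m0) + lam / (2.0 * s * kappa)
    lo = m0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14 * max(1.0, z):
            break
    b2 = 0.5 * (lo + hi)
    f_b2 = s * (b2 - z) ** 2 + lam * (1.0 - math.exp(-b2 / kappa))
    f_0 = s * z * z
    return sign * b2 if f_b2 < f_0 else 0.0


def _scad_threshold(z: float, s: float, lam: float, alpha: float) -> float:
    """Global minimizer of s*(z-b)^2 + SCAD(b); piecewise-quadratic pieces
    are solved exactly and compared (ties go to 0)."""
    if lam == 0.0 or z == 0.0:
        return z
    sign = 1.0 if z > 0 else -1.0
    z = abs(z)
    cands = [0.0, lam, alpha * lam]
    # piece 1: b in [0, lam], derivative 2s(b-z) + lam
    cands.append(min(max(z - lam / (2.0 * s), 0.0), lam))
    # piece 2: b in [lam, alpha*lam], derivative 2s(b-z) + (alpha*lam-b)/(alpha-1)
    denom = 2.0 * s - 1.0 / (alpha - 1.0)
    if denom > 0.0:
        b = (2.0 * s * z - alpha * lam / (alpha - 1.0)) / denom
        cands.append(min(max(b, lam), alpha * lam))
    # piece 3: b >= alpha*lam, flat penalty
    cands.append(max(z, alpha * lam))

    spec = PenaltySpec("scad", lam, alpha=alpha)
    best, best_f = 0.0, s * z * z
    for b in cands:
        f = s * (b - z) ** 2 + float(penalty_value(b, spec))
        if f < best_f - 0.0:  # strict improvement only: ties resolve to 0
            best, best_f = b, f
    return sign * best


def scalar_threshold(z: float, scale: float, spec: PenaltySpec) -> float:
    """Solve the univariate subproblem
    ``argmin_b 0.5 * scale * (z - b)**2 + p_lambda(b)`` exactly.

    This is the building block of coordinate descent.  For the lasso it is
    the soft-threshold operator; for SCAD and LEP all stationary points
    (including ``b = 0``) are enumerated and the global minimizer returned,
    with exact ties resolved to 0 in favor of sparsity.

    The result is odd in ``z`` and never overshoots: ``|result| <= |z|``
    with matching sign.
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    s = 0.5 * scale  # internal convention: s*(z-b)^2 + penalty
    if spec.family == "lasso":
        thr = spec.lam / (2.0 * s)
        return math.copysign(max(abs(z) - thr, 0.0), z) if abs(z) > thr else 0.0
    if spec.family == "lep":
        return _lep_threshold(float(z), s, spec.lam, spec.kappa)
    return _scad_threshold(float(z), s, spec.lam, spec.alpha)
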