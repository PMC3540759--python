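"""Compiled coordinate-descent kernels.

Everything here works on *standardized* design matrices: an (n, m) predictor
matrix with centered columns and a centered response.  The objective is the
plain sum of squared residuals plus the penalty (no 1/2 or 1/n factor):

    ||y - X beta||^2  +  sum_k p_lambda(beta_k)

so the univariate subproblem for coordinate k is
``s_k (z - b)^2 + p_lambda(b)`` with ``s_k = ||x_k||^2``.

The kernels are jitted with numba when available and fall back to the same
pure-Python code otherwise (identical numerics, just slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

# family codes (kept in sync with penalties.FAMILY_CODES)
LASSO, LEP, SCAD = 0, 1, 2


@njit(cache=True)
def _pen_value(b, family, lam, kappa, alpha):
    ab = abs(b)
    if family == LASSO:
        return lam * ab
    if family == LEP:
        return lam * (1.0 - math.exp(-ab / kappa))
    # SCAD
    if ab <= lam:
        return lam * ab
    if ab <= alpha * lam:
        return lam * lam + (alpha * lam * (ab - lam) - 0.5 * (ab * ab - lam * lam)) / (
            alpha - 1.0
        )
    return 0.5 * lam * lam * (alpha + 1.0)


@njit(cache=True)
def _threshold(z, s, family, lam, kappa, alpha):
    """argmin_b s*(z-b)^2 + p_lambda(b); exact ties resolve to 0."""
    if lam == 0.0 or z == 0.0:
        return z
    if family == LASSO:
        thr = lam / (2.0 * s)
        az = abs(z)
        if az <= thr:
            return 0.0
        return (az - thr) if z > 0.0 else -(az - thr)

    sign = 1.0 if z > 0.0 else -1.0
    az = abs(z)

    if family == LEP:
        # derivative on b>0: h(b) = 2s(b-az) + (lam/kappa) exp(-b/kappa), convex
        arg = lam / (2.0 * s * kappa * kappa)
        m0 = kappa * math.log(arg) if arg > 1.0 else 0.0
        h_m0 = 2.0 * s * (m0 - az) + (lam / kappa) * math.exp(-m0 / kappa)
        if h_m0 >= 0.0:
            return 0.0
        lo = m0
        hi = max(az, m0) + lam / (2.0 * s * kappa)
        # safeguarded Newton from the right (h convex, h(hi) > 0)
        b = hi
        for _ in range(100):
            hb = 2.0 * s * (b - az) + (lam / kappa) * math.exp(-b / kappa)
            if hb < 0.0:
                lo = b
            else:
                hi = b
            dh = 2.0 * s - (lam / (kappa * kappa)) * math.exp(-b / kappa)
            if dh > 0.0:
                bn = b - hb / dh
            else:
                bn = 0.5 * (lo + hi)
            if bn <= lo or bn >= hi:
                bn = 0.5 * (lo + hi)
            if abs(bn - b) < 1e-15 * (1.0 + az):
                b = bn
                break
            b = bn
        f_b = s * (b - az) ** 2 + lam * (1.0 - math.exp(-b / kappa))
        f_0 = s * az * az
        if f_b < f_0:
            return sign * b
        return 0.0

    # SCAD: enumerate per-piece stationary points and boundaries
    best = 0.0
    best_f = s * az * az
    n_c = 0
    cands = np.empty(6)
    cands[n_c] = lam
    n_c += 1
    cands[n_c] = alpha * lam
    n_c += 1
    b1 = az - lam / (2.0 * s)
    if b1 < 0.0:
        b1 = 0.0
    elif b1 > lam:
        b1 = lam
    cands[n_c] = b1
    n_c += 1
    denom = 2.0 * s - 1.0 / (alpha - 1.0)
    if denom > 0.0:
        b2 = (2.0 * s * az - alpha * lam / (alpha - 1.0)) / denom
        if b2 < lam:
            b2 = lam
        elif b2 > alpha * lam:
            b2 = alpha * lam
        cands[n_c] = b2
        n_c += 1
    cands[n_c] = az if az > alpha * lam else alpha * lam
    n_c += 1
    for idx in range(n_c):
        b = cands[idx]
        f = s * (b - az) ** 2 + _pen_value(b, SCAD, lam, kappa, alpha)
        if f < best_f:
            best = b
            best_f = f
    return sign * best


@njit(cache=True)
def _cd_sweep(X, r, beta, colss, family, lam, kappa, alpha):
    """One cyclic sweep; updates r and beta in place; returns max |change|."""
    n, m = X.shape
    delta = 0.0
    for k in range(m):
        s = colss[k]
        if s <= 0.0:
            continue
        bk = beta[k]
        rho = bk * s
        for j in range(n):
            rho += X[j, k] * r[j]
        z = rho / s
        bn = _threshold(z, s, family, lam, kappa, alpha)
        if bn != bk:
            d = bk - bn
            for j in range(n):
                r[j] += d * X[j, k]
            beta[k] = bn
            if abs(d) > delta:
                delta = abs(d)
    return delta


@njit(cache=True)
def _cd_solve(X, r, beta, colss, family, lam, kappa, alpha, max_iter, tol):
    """Run sweeps to convergence; returns (n_iter, converged)."""
    it = 0
    conv = False
    while it < max_iter:
        delta = _cd_sweep(X, r, beta, colss, family, lam, kappa, alpha)
        it += 1
        if delta < tol:
            conv = True
            break
    return it, conv


@njit(cache=True)
def _objective(r, beta, family, lam, kappa, alpha):
    obj = 0.0
    for j in range(r.shape[0]):
        obj += r[j] * r[j]
    for k in range(beta.shape[0]):
        if beta[k] != 0.0:
            obj += _pen_value(beta[k], family, lam, kappa, alpha)
    return obj


@njit(cache=True)
def _residual(X, y, beta):
    n, m = X.shape
    r = y.copy()
    for k in range(m):
        bk = beta[k]
        if bk != 0.0:
            for j in range(n):
                r[j] -= bk * X[j, k]
    return r


@njit(cache=True)
def cd_path(X, y, colss, lambdas, family, kappa, alpha, max_iter, tol, from_zeros):
    """Solve the penalized neighborhood regression along a lambda path.

    For the lasso the path is warm-started from the previous solution.  For
    nonconvex families each lambda is solved twice -- warm-started from the
    previous nonconvex solution and from the lasso solution at the same
    lambda -- and the lower-objective stationary point is kept.  With
    ``from_zeros`` the nonconvex solve starts cold from the zero vector
    instead (single-lambda diagnostic mode).

    Returns (coefs[L, m], ssr[L], n_iter[L], converged[L]).
    """
    n, m = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, m))
    ssrs = np.empty(L)
    iters = np.zeros(L, dtype=np.int64)
    convs = np.zeros(L, dtype=np.bool_)

    beta_l = np.zeros(m)  # lasso path state
    r_l = y.copy()
    beta_n = np.zeros(m)  # nonconvex path state
    r_n = y.copy()

    for li in range(L):
        lam = lambdas[li]
        it_l, cv_l = 0, False
        if family == LASSO or not from_zeros:
            it_l, cv_l = _cd_solve(
                X, r_l, beta_l, colss, LASSO, lam, kappa, alpha, max_iter, tol
            )
        if family == LASSO:
            coefs[li] = beta_l
            ssrs[li] = _objective(r_l, beta_l, LASSO, 0.0, kappa, alpha)
            iters[li] = it_l
            convs[li] = cv_l
            continue

        if from_zeros:
            beta_n[:] = 0.0
            r_n[:] = y
            it_a, cv_a = _cd_solve(
                X, r_n, beta_n, colss, family, lam, kappa, alpha, max_iter, tol
            )
            coefs[li] = beta_n
            ssrs[li] = _objective(r_n, beta_n, LASSO, 0.0, kappa, alpha)
            iters[li] = it_a
            convs[li] = cv_a
            continue

        # candidate A: warm start from previous lambda's nonconvex solution
        it_a, cv_a = _cd_solve(
            X, r_n, beta_n, colss, family, lam, kappa, alpha, max_iter, tol
        )
        obj_a = _objective(r_n, beta_n, family, lam, kappa, alpha)
        # candidate B: start from the lasso solution at this lambda
        beta_b = beta_l.copy()
        r_b = _residual(X, y, beta_b)
        it_b, cv_b = _cd_solve(
            X, r_b, beta_b, colss, family, lam, kappa, alpha, max_iter, tol
        )
        obj_b = _objective(r_b, beta_b, family, lam, kappa, alpha)
        if obj_b <= obj_a:
            beta_n[:] = beta_b
            r_n[:] = r_b
            iters[li] = it_l + it_b
            convs[li] = cv_b
        else:
            iters[li] = it_l + it_a
            convs[li] = cv_a
        coefs[li] = beta_n
        ssrs[li] = _objective(r_n, beta_n, LASSO, 0.0, kappa, alpha)
    return coefs, ssrs, iters, convs
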