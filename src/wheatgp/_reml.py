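"""Restricted maximum likelihood for variance-component models.

Two solvers share the same restricted likelihood:

* :func:`reml_dense` — generic path for y = Xb + sum_t u_t + e with
  u_t ~ N(0, s2_t K_t) for arbitrary PSD structures K_t; dense algebra,
  intended for n up to a few thousand.
* :func:`reml_balanced_classes` — exact reduction for balanced designs
  whose covariance is simultaneously diagonalized by orthogonal contrasts
  (complete crossed grids). The restricted likelihood then depends on the
  data only through per-stratum sums of squares, so each objective
  evaluation is O(#strata).

Both enforce non-negativity through L-BFGS-B box constraints, matching the
convention that variance components are reported as zero rather than
negative.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

from .exceptions import NumericalError

_EPS = 1e-10


def _restricted_nll_dense(theta, y, X, structures, n, p):
    """-2x restricted log-likelihood (up to constant) and its gradient."""
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], structures):
        V += t * K
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as e:
        raise NumericalError(f"covariance matrix not PD at theta={theta}") from e
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    try:
        cx = linalg.cho_factor(XtVinvX, check_finite=False)
    except linalg.LinAlgError as e:
        cond = np.linalg.cond(XtVinvX)
        raise NumericalError(
            f"singular fixed-effect system (condition number {cond:.3g})"
        ) from e
    logdet_X = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = linalg.cho_solve(cx, VinvX.T @ y, check_finite=False)
    Py = Vinv @ y - VinvX @ beta
    P = Vinv - VinvX @ linalg.cho_solve(cx, VinvX.T, check_finite=False)
    nll = logdet_V + logdet_X + float(y @ Py)
    grad = np.empty_like(theta)
    for i, K in enumerate(list(structures) + [np.eye(n)]):
        KPy = K @ Py
        grad[i] = float(np.sum(P * K) - Py @ KPy)
    return nll, grad, beta


def reml_dense(y, X, structures, lower=0.0, start=None):
    """REML estimates for arbitrary covariance structures.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (full column rank)
    structures : list of (n, n) PSD matrices, one per non-residual component
    lower : lower bound for each variance (0 enforces non-negativity)

    Returns
    -------
    theta : (k+1,) variances, residual last
    beta : GLS fixed effects at the optimum
    nll : -2 restricted log-likelihood (up to a constant)
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    k = len(structures)
    vy = float(np.var(y)) or 1.0
    if start is None:
        start = np.full(k + 1, vy / (k + 1))
    start = np.maximum(np.asarray(start, dtype=float), vy * 1e-6)
    bounds = [(lower, None)] * k + [(max(lower, vy * 1e-8), None)]

    def fun(theta):
        nll, grad, _ = _restricted_nll_dense(theta, y, X, structures, n, p)
        return nll, grad

    res = optimize.minimize(
        fun, start, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    theta = np.maximum(res.x, 0.0)
    nll, _, beta = _restricted_nll_dense(
        np.maximum(theta, vy * 1e-12), y, X, structures, n, p
    )
    return theta, beta, float(nll)


def reml_balanced_classes(ss, df, coeffs, extra_ss=0.0, extra_df=0.0,
                          residual_index=None):
    """REML for balanced designs via stratum sums of squares.

    The restricted likelihood of a balanced crossed design factors into
    independent strata: stratum s contributes df_s quadratic contrasts with
    common variance v_s(theta) = sum_j coeffs[s, j] * theta_j, observed sum
    of squares ss[s]. ``extra_ss``/``extra_df`` fold in a pure-residual
    stratum (e.g. within-cell replication) whose variance is theta[-1].

    Parameters
    ----------
    ss : (S,) stratum sums of squares
    df : (S,) stratum degrees of freedom
    coeffs : (S, k) matrix: v_s = coeffs[s] @ theta
    residual_index : column of ``coeffs`` that is the residual variance
        (defaults to the last)

    Returns
    -------
    theta : (k,) variance estimates (non-negative), nll
    """
    ss = np.asarray(ss, dtype=float)
    df = np.asarray(df, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    k = coeffs.shape[1]
    if residual_index is None:
        residual_index = k - 1
    tot = (ss.sum() + extra_ss) / max(df.sum() + extra_df, 1.0)
    if tot <= 0.0:  # constant data: every component is zero
        return np.zeros(k), 0.0

    def nll(theta):
        v = coeffs @ theta
        if np.any(v <= 0):
            return np.inf
        val = float(np.sum(df * np.log(v) + ss / v))
        if extra_df > 0:
            r = theta[residual_index]
            if r <= 0:
                return np.inf
            val += extra_df * np.log(r) + extra_ss / r
        return val

    # method-of-moments start: equate ss/df to v and solve least squares
    ms = ss / np.maximum(df, 1.0)
    start, *_ = np.linalg.lstsq(coeffs, ms, rcond=None)
    start = np.clip(start, tot * 1e-4, None)
    bounds = [(0.0, None)] * k
    bounds[residual_index] = (tot * 1e-10, None)
    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    theta = np.maximum(res.x, 0.0)
    return theta, float(res.fun)


def reml_lowrank_iid(y, X, Z, max_iter=200):
    """REML for V = s2_r Z Z' + s2_e I with low-rank Z (few columns).

    Used for the within-trial BLUE model (replicates random, genotypes
    fixed). Woodbury identities keep each evaluation at
    O(n q^2 + p^2 q + p^3) with q = Z columns, p = X columns.

    Returns (s2_r, s2_e), beta, cov_beta.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = X.shape
    q = Z.shape[1]
    ZtZ = Z.T @ Z
    XtX = X.T @ X
    XtZ = X.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    vy = float(np.var(y)) or 1.0

    def pieces(theta):
        s2r, s2e = theta
        gam = s2r / s2e
        # V^-1 = (1/s2e)(I - Z C Z'), C = (I/gam + Z'Z)^-1  (gam > 0)
        if gam > 0:
            C = np.linalg.inv(np.eye(q) / gam + ZtZ)
        else:
            C = np.zeros((q, q))
        logdet_V = n * np.log(s2e) + (
            np.linalg.slogdet(np.eye(q) + gam * ZtZ)[1] if gam > 0 else 0.0
        )
        XtVinvX = (XtX - XtZ @ C @ XtZ.T) / s2e
        XtVinvy = (Xty - XtZ @ C @ Zty) / s2e
        ytVinvy = (yty - Zty @ C @ Zty) / s2e
        sign, logdet_X = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            raise NumericalError("singular genotype design in BLUE model")
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        quad = ytVinvy - float(XtVinvy @ beta)
        return logdet_V + logdet_X + quad, beta, XtVinvX

    def fun(theta):
        return pieces(theta)[0]

    res = optimize.minimize(
        fun, x0=np.array([vy / 4, vy / 2]), method="L-BFGS-B",
        bounds=[(0.0, None), (vy * 1e-8, None)],
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    theta = np.maximum(res.x, 0.0)
    _, beta, XtVinvX = pieces(np.maximum(theta, [0.0, vy * 1e-10]))
    cov_beta = np.linalg.inv(XtVinvX)
    return theta, beta, cov_beta
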