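"""Gauss-Newton least squares with Levenberg damping and box bounds.

A compact trust-region-flavoured engine for the handful-of-parameters
fits this package performs. Residual functions return the (already
weighted) residual vector; the objective is its sum of squares. Steps
solve the damped normal equations (J'J + lam*diag(J'J)) dp = -J'r and are
accepted only when the objective decreases, so the sequence of accepted
objectives is non-increasing by construction. Bounds are enforced by
projection. Jacobians are central finite differences with step
1e-6 * max(|p|, 1) per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LMResult:
    params: np.ndarray
    objective: float
    converged: bool
    n_iterations: int
    covariance: np.ndarray | None
    message: str
    residuals: np.ndarray = field(default=None, repr=False)
    jacobian: np.ndarray = field(default=None, repr=False)


def _project(p, lower, upper):
    return np.minimum(np.maximum(p, lower), upper)


def numerical_jacobian(fun, p, lower=None, upper=None):
    """Central-difference Jacobian of a residual function at p."""
    p = np.asarray(p, dtype=float)
    r0 = np.asarray(fun(p))
    jac = np.empty((r0.size, p.size))
    for j in range(p.size):
        h = 1e-6 * max(abs(p[j]), 1.0)
        pp, pm = p.copy(), p.copy()
        pp[j] += h
        pm[j] -= h
        if lower is not None:
            # one-sided fallback when the centred stencil leaves the box
            if pp[j] > upper[j]:
                pp[j] = p[j]
            if pm[j] < lower[j]:
                pm[j] = p[j]
        denom = pp[j] - pm[j]
        jac[:, j] = (np.asarray(fun(pp)) - np.asarray(fun(pm))) / denom
    return jac


def levenberg_least_squares(
    fun,
    p0,
    lower,
    upper,
    max_iterations: int = 500,
    convergence_tol: float = 1e-10,
    step_tol: float = 1e-10,
    damping: float = 1e-3,
    pure_gauss_newton: bool = False,
    callback=None,
) -> LMResult:
    """Minimize sum(fun(p)**2) subject to lower <= p <= upper.

    ``damping`` is the initial Levenberg factor; with
    ``pure_gauss_newton`` the damping stays at zero (the classical
    Gauss-Newton iteration). Never raises on non-convergence: the result
    carries an honest ``converged`` flag.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    p = _project(np.asarray(p0, dtype=float).copy(), lower, upper)
    r = np.asarray(fun(p))
    obj = float(r @ r)
    lam = 0.0 if pure_gauss_newton else damping
    converged = False
    message = "maximum iterations reached"
    n_iter = 0

    for n_iter in range(1, max_iterations + 1):
        jac = numerical_jacobian(fun, p, lower, upper)
        jtj = jac.T @ jac
        g = jac.T @ r
        accepted = False
        for _ in range(60):
            if pure_gauss_newton:
                aug = jtj
            else:
                d = np.diag(jtj).copy()
                d[d <= 0] = 1.0
                aug = jtj + lam * np.diag(d)
            try:
                step = np.linalg.solve(aug, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(aug, -g, rcond=None)[0]
            p_new = _project(p + step, lower, upper)
            r_new = np.asarray(fun(p_new))
            obj_new = float(r_new @ r_new)
            if obj_new <= obj:
                accepted = True
                break
            if pure_gauss_newton:
                break
            lam *= 10.0
        if not accepted:
            message = "no decreasing step found"
            converged = obj <= convergence_tol  # already at (near-)zero residual
            if converged:
                message = "objective at residual floor"
            break
        step_norm = float(np.linalg.norm(p_new - p))
        rel_change = abs(obj - obj_new) / max(obj, 1e-300)
        p, r, obj = p_new, r_new, obj_new
        if not pure_gauss_newton:
            lam = max(lam / 10.0, 1e-12)
        if callback is not None:
            callback(p, obj)
        if rel_change < convergence_tol or step_norm < step_tol:
            converged = True
            message = "converged"
            break

    jac = numerical_jacobian(fun, p, lower, upper)
    cov = _covariance(jac, obj, r.size)
    return LMResult(
        params=p,
        objective=obj,
        converged=converged,
        n_iterations=n_iter,
        covariance=cov,
        message=message,
        residuals=r,
        jacobian=jac,
    )


def _covariance(jac, objective, n_obs):
    """Residual-variance-scaled inverse normal-equations matrix, or None."""
    n_par = jac.shape[1]
    dof = n_obs - n_par
    if dof <= 0:
        return None
    jtj = jac.T @ jac
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(inv)):
        return None
    return inv * (objective / dof)
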