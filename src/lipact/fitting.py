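"""Global and minimal-model fitting.

Two scikit-learn-style estimators do the work:

* :class:`TwoStageGlobalModel` — joint weighted least-squares fit of the
  two-stage activity model and the FRET observation model with a shared
  exchange constant. ``X`` is (n, 2) micellar composition columns
  ``[x_lipid, x_probe]``, ``y`` the observed activity or efficiency, and
  ``kind`` labels each row ``"activity"`` or ``"fret"``.
* :class:`MinimalActivityModel` — four-parameter logistic in the mole
  fraction, fit to activity data alone.

Because activity (umol Pi/mg/min, range ~12) and transfer efficiency
(dimensionless, range <1) are incommensurate, the default global
weighting is inverse-variance: each dataset is first fit alone, its
residual variance estimated, and one re-weighted joint pass performed.
Standard errors come from the residual-variance-scaled inverse
normal-equations matrix. Module-level functions (``fit_global``,
``fit_minimal``, ...) are thin wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .activity import (
    LogisticStageParams,
    MinimalParams,
    TwoStageParams,
    activity_from_composition,
    minimal_activity,
)
from .composition import ActivityObservation, FretObservation, micellar_mole_fraction
from .exchange import ExchangeParams
from .fret import FretParams, predicted_efficiency
from .optimize import levenberg_least_squares

GLOBAL_PARAM_NAMES = ("a0", "a1", "theta05", "c_theta", "k_ex", "xi")
MINIMAL_PARAM_NAMES = ("a0", "a1", "x05", "c_x")

_DEFAULT_BOUNDS = {
    "a0": (0.0, 1e6),
    "a1": (1e-6, 1e6),
    "theta05": (1e-3, 0.999),
    "x05": (1e-3, 0.999),
    "c_theta": (1e-6, 1e6),
    "c_x": (1e-6, 1e6),
    "k_ex": (1e-3, 1e3),
    "xi": (1e-3, 1e4),
}


class UnderdeterminedDesignError(ValueError):
    """The titration design cannot identify the model parameters."""


@dataclass
class FitOptions:
    """Optimizer settings shared by both estimators."""

    max_iterations: int = 500
    convergence_tol: float = 1e-10
    step_tol: float = 1e-10
    damping: float = 1e-3
    pure_gauss_newton: bool = False
    weights: str = "inverse_variance"  # or "unit"
    bounds: Optional[dict] = None  # per-parameter (lower, upper) overrides

    def __post_init__(self):
        if self.convergence_tol <= 0 or self.step_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.weights not in ("inverse_variance", "unit"):
            raise ValueError("weights must be 'inverse_variance' or 'unit'")
        if self.bounds:
            for name, (lo, hi) in self.bounds.items():
                if lo >= hi:
                    raise ValueError(f"bounds for {name}: lower must be < upper")


@dataclass
class GlobalFitResult:
    """Joint activity + FRET fit: estimates, uncertainties, diagnostics."""

    estimates: dict
    standard_errors: dict
    covariance: Optional[np.ndarray]
    residuals: pd.DataFrame
    objective: float
    converged: bool
    n_iterations: int
    weights: dict = field(default_factory=dict)
    message: str = ""

    @property
    def two_stage_params(self) -> TwoStageParams:
        e = self.estimates
        return TwoStageParams(
            stage2=LogisticStageParams(e["a0"], e["a1"], e["theta05"], e["c_theta"]),
            stage1=ExchangeParams(e["k_ex"], beta=e.get("beta", 2)),
        )

    @property
    def fret_params(self) -> FretParams:
        return FretParams(self.estimates["xi"], self.two_stage_params.stage1)


@dataclass
class MinimalFitResult:
    estimates: dict
    standard_errors: dict
    covariance: Optional[np.ndarray]
    residuals: pd.DataFrame
    objective: float
    converged: bool
    n_iterations: int
    message: str = ""

    @property
    def params(self) -> MinimalParams:
        e = self.estimates
        return MinimalParams(e["a0"], e["a1"], e["x05"], e["c_x"])


# ---------------------------------------------------------------------------
# raw vectorized model evaluations (no dataclass validation: the optimizer
# may probe parameter vectors that individual invariants would reject)

def _coverage_raw(x, k, beta, variant):
    num = k * (x ** beta if variant == "symmetric" else x)
    return num / ((1.0 - x) ** beta + num)


def _logistic_raw(z, a0, a1, z05, c):
    with np.errstate(over="ignore"):
        return a0 + (a1 - a0) / (1.0 + np.exp(-c * (z - z05)))


def _activity_raw(x, p, beta, variant):
    a0, a1, t05, c = p[:4]
    return _logistic_raw(_coverage_raw(x, p[4], beta, variant), a0, a1, t05, c)


def _efficiency_raw(xl, xp, k_ex, xi, beta, variant):
    xd = 1.0 - xl - xp
    theta_probe = k_ex * xp / (xd ** beta + k_ex * (xp + xl))
    z = xi * theta_probe
    return z / (1.0 + z)


# ---------------------------------------------------------------------------
# initialization

def _init_from_arrays(x, y, beta=2, variant="single"):
    """Heuristic start values from an activity titration (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise UnderdeterminedDesignError("need at least 3 distinct abscissae")
    # bin abscissae so finite differences are taken between well-separated
    # composition levels; replicate scatter at near-identical x would
    # otherwise produce runaway slope estimates
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    min_dx = 0.02 * float(np.ptp(xs))
    ux, my = [], []
    i = 0
    while i < xs.size:
        j = i
        while j + 1 < xs.size and xs[j + 1] - xs[i] < min_dx:
            j += 1
        ux.append(xs[i : j + 1].mean())
        my.append(ys[i : j + 1].mean())
        i = j + 1
    ux, my = np.asarray(ux), np.asarray(my)
    if ux.size < 3:
        raise UnderdeterminedDesignError("need at least 3 distinct abscissae")
    a0 = float(y.min())
    a1 = float(y.max())
    if a1 - a0 < 1e-12:
        raise ValueError("degenerate design: constant activities")
    mid = 0.5 * (a0 + a1)
    x_mid = float(ux[np.argmin(np.abs(my - mid))])
    x_mid = min(max(x_mid, 1e-3), 0.999)
    theta_mid = float(_coverage_raw(np.array(x_mid), 1.0, beta, variant))
    theta_mid = min(max(theta_mid, 1e-3), 0.999)
    dx = np.diff(ux)
    slopes_x = np.diff(my) / dx
    theta_grid = _coverage_raw(ux, 1.0, beta, variant)
    dth = np.diff(theta_grid)
    slopes_t = np.diff(my) / np.where(dth == 0, np.inf, dth)
    s_x = float(np.max(slopes_x))
    s_t = float(np.max(slopes_t))
    if s_x <= 0:
        # no rising segment (model-mismatched data): start from a shallow
        # logistic and let the optimizer park the slope at its bound
        c_x0 = c_t0 = 1.0
    else:
        c_x0 = 4.0 * s_x / (a1 - a0)
        c_t0 = 4.0 * max(s_t, s_x) / (a1 - a0)
    return {
        "a0": a0,
        "a1": a1,
        "x05": x_mid,
        "theta05": theta_mid,
        "c_x": c_x0,
        "c_theta": c_t0,
        "k_ex": 1.0,
    }


def default_initialization(
    activity_data: list[ActivityObservation],
    fret_data: Optional[list[FretObservation]] = None,
    beta: int = 2,
    variant: str = "single",
) -> dict:
    """Deterministic start values from the data.

    a0/a1 from the activity extremes, the half-activation abscissa from
    the observation nearest mid-activity, the cooperativity coefficient
    from the steepest finite-difference slope, K_ex = 1, and xi inverted
    from the largest observed efficiency under K_ex = 1.
    """
    if not activity_data:
        raise ValueError("activity data must be nonempty")
    x = np.array(
        [micellar_mole_fraction(o.totals).x_lipid for o in activity_data]
    )
    y = np.array([o.activity for o in activity_data])
    init = _init_from_arrays(x, y, beta=beta, variant=variant)
    if fret_data:
        e = np.array([o.e_app for o in fret_data])
        i = int(np.argmax(e))
        comp = fret_data[i].composition
        theta_h = _efficiency_theta(comp, beta, variant)
        e_max = min(max(float(e[i]), 1e-6), 1 - 1e-6)
        init["xi"] = e_max / (max(theta_h, 1e-9) * (1.0 - e_max))
    else:
        init["xi"] = 50.0
    return init


def _efficiency_theta(comp, beta, variant):
    xd = 1.0 - comp.x_lipid - comp.x_probe
    return comp.x_probe / (xd ** beta + (comp.x_probe + comp.x_lipid))


# ---------------------------------------------------------------------------
# objective (public, observation-level)

def weighted_objective(
    params: tuple[TwoStageParams, FretParams],
    activity_data: list[ActivityObservation],
    fret_data: list[FretObservation],
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Weighted sum of squared deviations over both datasets."""
    if not activity_data or not fret_data:
        raise ValueError("both datasets must be nonempty")
    two_stage, fret = params
    w_a, w_f = weights
    obj = 0.0
    for o in activity_data:
        x = micellar_mole_fraction(o.totals).x_lipid
        obj += w_a * (o.activity - activity_from_composition(x, two_stage)) ** 2
    for o in fret_data:
        obj += w_f * (o.e_app - predicted_efficiency(o.composition, fret)) ** 2
    return obj


# ---------------------------------------------------------------------------
# estimators

def _bounds_vectors(names, overrides):
    bounds = dict(_DEFAULT_BOUNDS)
    if overrides:
        bounds.update(overrides)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    return lo, hi


def _stderr_from_cov(cov, names):
    if cov is None:
        return {n: float("nan") for n in names}
    var = np.diag(cov)
    return {
        n: float(np.sqrt(v)) if v >= 0 else float("nan")
        for n, v in zip(names, var)
    }


class TwoStageGlobalModel(BaseEstimator):
    """Global fit of the two-stage activity model and the FRET model.

    Parameters
    ----------
    beta : int
        Exchange stoichiometry (detergent molecules displaced per lipid).
    variant : str
        Isotherm variant, ``"single"`` (default) or ``"symmetric"``.
    init : dict, optional
        Overrides for individual start values (merged over the
        data-driven defaults).
    options : FitOptions, optional
    multi_start : int
        Number of additional perturbed starts (0 = deterministic single
        start).
    random_state : int, optional
        Seed for the multi-start perturbations.

    Attributes (after fit)
    ----------------------
    a0_, a1_, theta05_, c_theta_, k_ex_, xi_ : float estimates;
    stderr_ : dict of asymptotic standard errors;
    covariance_ : parameter covariance matrix;
    residuals_ : per-observation DataFrame tagged by dataset;
    objective_, converged_, n_iter_, weights_.
    """

    def __init__(
        self,
        beta: int = 2,
        variant: str = "single",
        init: Optional[dict] = None,
        options: Optional[FitOptions] = None,
        multi_start: int = 0,
        random_state: Optional[int] = None,
    ):
        self.beta = beta
        self.variant = variant
        self.init = init
        self.options = options
        self.multi_start = multi_start
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _residual_fn(self, x_act, y_act, xl_f, xp_f, y_f, sw_a, sw_f):
        beta, variant = self.beta, self.variant

        def resid(p):
            ra = sw_a * (y_act - _activity_raw(x_act, p, beta, variant))
            rf = sw_f * (
                y_f - _efficiency_raw(xl_f, xp_f, p[4], p[5], beta, variant)
            )
            return np.concatenate([ra, rf])

        return resid

    def _run(self, resid, p0, opts, names=GLOBAL_PARAM_NAMES, free=None):
        lo, hi = _bounds_vectors(names, opts.bounds)
        if free is None:
            fun, p_start, lo_f, hi_f = resid, p0, lo, hi
            expand = lambda q: q
        else:
            free = np.asarray(free)
            fixed = np.asarray(p0, dtype=float)

            def expand(q):
                full = fixed.copy()
                full[free] = q
                return full

            fun = lambda q: resid(expand(q))
            p_start, lo_f, hi_f = fixed[free], lo[free], hi[free]
        res = levenberg_least_squares(
            fun,
            p_start,
            lo_f,
            hi_f,
            max_iterations=opts.max_iterations,
            convergence_tol=opts.convergence_tol,
            step_tol=opts.step_tol,
            damping=opts.damping,
            pure_gauss_newton=opts.pure_gauss_newton,
        )
        res.params = expand(res.params)
        return res

    # -- API -------------------------------------------------------------
    def fit(self, X, y, kind=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == 1:
            X = np.hstack([X, np.zeros_like(X)])
        y = np.asarray(y, dtype=float)
        if kind is None:
            kind = np.array(["activity"] * len(y))
        kind = np.asarray(kind)
        act = kind == "activity"
        fret = kind == "fret"
        n_a, n_f = int(act.sum()), int(fret.sum())
        if n_a < 8:
            raise UnderdeterminedDesignError(
                f"need >= 8 activity observations, got {n_a}"
            )
        if n_f < 6:
            raise UnderdeterminedDesignError(
                f"need >= 6 FRET observations, got {n_f}"
            )
        x_act, y_act = X[act, 0], y[act]
        xl_f, xp_f, y_f = X[fret, 0], X[fret, 1], y[fret]
        if np.unique(x_act).size < 3 or np.ptp(x_act) < 1e-9:
            raise UnderdeterminedDesignError(
                "activity design does not span the titration"
            )

        opts = self.options or FitOptions()
        init = _init_from_arrays(x_act, y_act, self.beta, self.variant)
        e_imax = int(np.argmax(y_f))
        xd = 1.0 - xl_f[e_imax] - xp_f[e_imax]
        th = xp_f[e_imax] / (xd ** self.beta + (xp_f[e_imax] + xl_f[e_imax]))
        e_max = min(max(float(y_f[e_imax]), 1e-6), 1 - 1e-6)
        init["xi"] = e_max / (max(th, 1e-9) * (1 - e_max))
        if self.init:
            init.update(self.init)
        p0 = np.array([init[n] for n in GLOBAL_PARAM_NAMES])

        ones_a, ones_f = np.ones(n_a), np.ones(n_f)
        if opts.weights == "inverse_variance":
            # preliminary per-dataset fits to estimate residual variances
            r_act = self._residual_fn(
                x_act, y_act, xl_f[:0], xp_f[:0], y_f[:0], ones_a, ones_f[:0]
            )
            pre_a = self._run(r_act, p0, opts, free=[0, 1, 2, 3, 4])
            r_fret = self._residual_fn(
                x_act[:0], y_act[:0], xl_f, xp_f, y_f, ones_a[:0], ones_f
            )
            pre_f = self._run(r_fret, pre_a.params, opts, free=[4, 5])
            s2_a = max(pre_a.objective / max(n_a - 5, 1), 1e-12)
            s2_f = max(pre_f.objective / max(n_f - 2, 1), 1e-12)
            w_a, w_f = 1.0 / s2_a, 1.0 / s2_f
            p_start = pre_a.params.copy()
            p_start[4:6] = pre_f.params[4:6]
        else:
            w_a = w_f = 1.0
            p_start = p0

        resid = self._residual_fn(
            x_act, y_act, xl_f, xp_f, y_f,
            np.sqrt(w_a) * ones_a, np.sqrt(w_f) * ones_f,
        )
        best = self._run(resid, p_start, opts)
        if self.multi_start:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.multi_start):
                trial = p_start * rng.lognormal(0.0, 0.3, size=p_start.size)
                cand = self._run(resid, trial, opts)
                if cand.converged and cand.objective < best.objective:
                    best = cand

        p = best.params
        for name, value in zip(GLOBAL_PARAM_NAMES, p):
            setattr(self, name + "_", float(value))
        self.params_ = dict(zip(GLOBAL_PARAM_NAMES, map(float, p)))
        self.covariance_ = best.covariance
        self.stderr_ = _stderr_from_cov(best.covariance, GLOBAL_PARAM_NAMES)
        fitted_a = _activity_raw(x_act, p, self.beta, self.variant)
        fitted_f = _efficiency_raw(xl_f, xp_f, p[4], p[5], self.beta, self.variant)
        self.residuals_ = pd.DataFrame(
            {
                "dataset": ["activity"] * n_a + ["fret"] * n_f,
                "x_lipid": np.concatenate([x_act, xl_f]),
                "x_probe": np.concatenate([np.zeros(n_a), xp_f]),
                "observed": np.concatenate([y_act, y_f]),
                "fitted": np.concatenate([fitted_a, fitted_f]),
                "residual": np.concatenate([y_act - fitted_a, y_f - fitted_f]),
                "weight": np.concatenate([w_a * ones_a, w_f * ones_f]),
            }
        )
        self.objective_ = best.objective
        self.converged_ = best.converged
        self.n_iter_ = best.n_iterations
        self.weights_ = {"activity": float(w_a), "fret": float(w_f)}
        self.message_ = best.message
        lo, hi = _bounds_vectors(GLOBAL_PARAM_NAMES, opts.bounds)
        self.at_bound_ = [
            n
            for n, v, l, h in zip(GLOBAL_PARAM_NAMES, p, lo, hi)
            if v - l < 1e-9 * max(abs(l), 1) or h - v < 1e-9 * max(abs(h), 1)
        ]
        return self

    def predict(self, X, kind=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == 1:
            X = np.hstack([X, np.zeros_like(X)])
        p = np.array([getattr(self, n + "_") for n in GLOBAL_PARAM_NAMES])
        if kind is None:
            kind = np.array(["activity"] * X.shape[0])
        kind = np.asarray(kind)
        out = np.empty(X.shape[0])
        act = kind == "activity"
        out[act] = _activity_raw(X[act, 0], p, self.beta, self.variant)
        out[~act] = _efficiency_raw(
            X[~act, 0], X[~act, 1], p[4], p[5], self.beta, self.variant
        )
        return out


class MinimalActivityModel(RegressorMixin, BaseEstimator):
    """Four-parameter logistic activity model in the micellar mole fraction."""

    def __init__(
        self,
        init: Optional[dict] = None,
        options: Optional[FitOptions] = None,
    ):
        self.init = init
        self.options = options

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if x.size < 5:
            raise UnderdeterminedDesignError(
                f"need >= 5 activity observations, got {x.size}"
            )
        opts = self.options or FitOptions()
        init = _init_from_arrays(x, y)
        if self.init:
            init.update(self.init)
        p0 = np.array([init[n] for n in MINIMAL_PARAM_NAMES])
        lo, hi = _bounds_vectors(MINIMAL_PARAM_NAMES, opts.bounds)

        def resid(p):
            return y - _logistic_raw(x, p[0], p[1], p[2], p[3])

        res = levenberg_least_squares(
            resid,
            p0,
            lo,
            hi,
            max_iterations=opts.max_iterations,
            convergence_tol=opts.convergence_tol,
            step_tol=opts.step_tol,
            damping=opts.damping,
            pure_gauss_newton=opts.pure_gauss_newton,
        )
        p = res.params
        for name, value in zip(MINIMAL_PARAM_NAMES, p):
            setattr(self, name + "_", float(value))
        self.params_ = dict(zip(MINIMAL_PARAM_NAMES, map(float, p)))
        self.covariance_ = res.covariance
        self.stderr_ = _stderr_from_cov(res.covariance, MINIMAL_PARAM_NAMES)
        fitted = _logistic_raw(x, *p)
        self.residuals_ = pd.DataFrame(
            {
                "dataset": "activity",
                "x_lipid": x,
                "observed": y,
                "fitted": fitted,
                "residual": y - fitted,
                "weight": 1.0,
            }
        )
        self.objective_ = res.objective
        self.converged_ = res.converged
        self.n_iter_ = res.n_iterations
        self.message_ = res.message
        self.at_bound_ = [
            n
            for n, v, l, h in zip(MINIMAL_PARAM_NAMES, p, lo, hi)
            if v - l < 1e-9 * max(abs(l), 1) or h - v < 1e-9 * max(abs(h), 1)
        ]
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return _logistic_raw(x, self.a0_, self.a1_, self.x05_, self.c_x_)


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators

def fit_global(
    activity_data: list[ActivityObservation],
    fret_data: list[FretObservation],
    init: Optional[dict] = None,
    options: Optional[FitOptions] = None,
    beta: int = 2,
    variant: str = "single",
    multi_start: int = 0,
    random_state: Optional[int] = None,
) -> GlobalFitResult:
    """Global weighted fit sharing K_ex between activity and FRET data."""
    x_a = [[micellar_mole_fraction(o.totals).x_lipid, 0.0] for o in activity_data]
    y_a = [o.activity for o in activity_data]
    x_f = [[o.composition.x_lipid, o.composition.x_probe] for o in fret_data]
    y_f = [o.e_app for o in fret_data]
    X = np.array(x_a + x_f)
    y = np.array(y_a + y_f)
    kind = np.array(["activity"] * len(y_a) + ["fret"] * len(y_f))
    est = TwoStageGlobalModel(
        beta=beta,
        variant=variant,
        init=init,
        options=options,
        multi_start=multi_start,
        random_state=random_state,
    ).fit(X, y, kind=kind)
    return GlobalFitResult(
        estimates=dict(est.params_, beta=beta),
        standard_errors=est.stderr_,
        covariance=est.covariance_,
        residuals=est.residuals_,
        objective=est.objective_,
        converged=est.converged_,
        n_iterations=est.n_iter_,
        weights=est.weights_,
        message=est.message_,
    )


def fit_minimal(
    activity_data: list[ActivityObservation],
    init: Optional[dict] = None,
    options: Optional[FitOptions] = None,
) -> MinimalFitResult:
    """Fit the minimal logistic-in-x model to activity data alone."""
    x = np.array([micellar_mole_fraction(o.totals).x_lipid for o in activity_data])
    y = np.array([o.activity for o in activity_data])
    est = MinimalActivityModel(init=init, options=options).fit(x, y)
    return MinimalFitResult(
        estimates=est.params_,
        standard_errors=est.stderr_,
        covariance=est.covariance_,
        residuals=est.residuals_,
        objective=est.objective_,
        converged=est.converged_,
        n_iterations=est.n_iter_,
        message=est.message_,
    )


def runs_test(signs: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on a sign sequence.

    Returns (z, p). z compares the observed number of runs with its
    expectation under exchangeability; p is the one-sided probability of
    seeing this few or fewer runs (small p flags clustered, i.e.
    systematically structured, residuals).
    """
    signs = np.asarray(signs)
    signs = signs[signs != 0]
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan")
    runs = 1 + int((signs[1:] != signs[:-1]).sum())
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return float("nan"), float("nan")
    z = (runs - mu) / np.sqrt(var)
    return float(z), float(norm.cdf(z))


def residual_diagnostics(result) -> dict:
    """Per-dataset residual summary with a runs test for sign randomness.

    Residual signs are ordered by fitted value before the runs test, so a
    lack-of-fit trend along the response shows up as too few runs.
    Datasets with fewer than 5 residuals are marked unreliable.
    """
    df = result.residuals
    out = {}
    for name, grp in df.groupby("dataset"):
        res = grp.sort_values("fitted")["residual"].to_numpy()
        z, p = runs_test(np.sign(res))
        out[name] = {
            "n": int(res.size),
            "mean": float(res.mean()),
            "sd": float(res.std(ddof=1)) if res.size > 1 else 0.0,
            "runs_z": z,
            "runs_p": p,
            "unreliable": res.size < 5,
        }
    return out
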