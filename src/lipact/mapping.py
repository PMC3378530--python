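"""Mapping between two-stage and minimal-model parameters.

Sweeps one two-stage parameter at a time, simulates noise-free activity
curves over the full composition range, fits the minimal logistic-in-x
model to each curve, and summarizes how the fitted half-activation
fraction X0.5 and cooperativity c_x track the swept parameter. The
characteristic findings: c_x is linear in K_ex (so the maximal slope of
the activation curve reads out relative lipid affinity), X0.5 is
quasi-linear in theta05, and the cross-dependencies are comparatively
small.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import linregress

from .activity import LogisticStageParams, TwoStageParams, activity_from_composition
from .exchange import ExchangeParams
from .fitting import FitOptions, MinimalActivityModel

TABLE_TWO_STAGE = TwoStageParams(
    stage2=LogisticStageParams(a0=1.1, a1=12.8, theta05=0.16, c_theta=15.0),
    stage1=ExchangeParams(k_ex=1.4, beta=2),
)

DEFAULT_GRIDS = {
    "k_ex": (0.5, 0.75, 1.0, 1.4, 2.0, 2.5, 3.0),
    "theta05": (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40),
    "c_theta": (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter-at-a-time sweep specification."""

    varied_name: str
    grid: tuple = None
    base: TwoStageParams = TABLE_TWO_STAGE
    x_grid: tuple = tuple(np.linspace(0.0, 1.0, 101))

    def __post_init__(self):
        if self.varied_name not in ("k_ex", "theta05", "c_theta"):
            raise ValueError("varied_name must be k_ex, theta05 or c_theta")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.varied_name])
        xg = np.asarray(self.x_grid, dtype=float)
        if np.any(xg < 0) or np.any(xg > 1):
            raise ValueError("x_grid must lie in [0, 1]")

    def params_at(self, value: float) -> TwoStageParams:
        if self.varied_name == "k_ex":
            return replace(
                self.base, stage1=replace(self.base.stage1, k_ex=value)
            )
        return replace(
            self.base, stage2=replace(self.base.stage2, **{self.varied_name: value})
        )


@dataclass(frozen=True)
class SweepRecord:
    varied_value: float
    fitted_x05: float
    fitted_c_x: float
    fit_objective: float
    converged: bool


def run_sweep(spec: SweepSpec, fit_options: FitOptions | None = None) -> list[SweepRecord]:
    """Simulate noise-free activity at each grid value and fit the minimal model."""
    x = np.asarray(spec.x_grid, dtype=float)
    records = []
    for value in spec.grid:
        truth = spec.params_at(float(value))
        y = activity_from_composition(x, truth)
        est = MinimalActivityModel(options=fit_options).fit(x, y)
        records.append(
            SweepRecord(
                varied_value=float(value),
                fitted_x05=est.x05_,
                fitted_c_x=est.c_x_,
                fit_objective=est.objective_,
                converged=est.converged_,
            )
        )
    return records


def linearity_summary(
    records: list[SweepRecord],
    x_name: str = "varied_value",
    y_name: str = "fitted_c_x",
) -> dict:
    """OLS line through converged sweep records with R^2."""
    pts = [
        (getattr(r, x_name), getattr(r, y_name)) for r in records if r.converged
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 converged records")
    xs, ys = zip(*pts)
    fit = linregress(xs, ys)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "n": len(pts),
    }
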