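"""Stage 1: Langmuir-type amphiphile exchange at the transmembrane surface.

A double-chain phospholipid displaces ``beta`` single-chain detergent
molecules from the boundary monolayer surrounding the protein's
transmembrane region. At equilibrium the fractional coverage of that
surface by lipid is

    theta = K_ex * x / ((1 - x)**beta + K_ex * x)

where x is the lipid mole fraction in the micellar phase and K_ex the
exchange (relative-affinity) constant, i.e. the ratio of the
adsorption/desorption coefficient quotients of lipid and reference
detergent. K_ex > 1 means the lipid binds the transmembrane surface more
avidly than the detergent. The symmetric variant
K*x**beta / ((1-x)**beta + K*x**beta) is available as ``variant="symmetric"``
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import MicellarComposition

_VARIANTS = ("single", "symmetric")


@dataclass(frozen=True)
class ExchangeParams:
    """Exchange constant and stoichiometry of the lipid/detergent swap."""

    k_ex: float
    beta: int = 2
    variant: str = "single"

    def __post_init__(self):
        if self.k_ex <= 0:
            raise ValueError("k_ex must be positive")
        if not (isinstance(self.beta, (int, np.integer)) and 1 <= self.beta <= 4):
            raise ValueError("beta must be an integer in 1..4")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")


@dataclass(frozen=True)
class RateCoefficients:
    """Adsorption/desorption rate coefficients of lipid and reference."""

    k_ad_lipid: float
    k_d_lipid: float
    k_ad_ref: float
    k_d_ref: float

    def __post_init__(self):
        if min(self.k_ad_lipid, self.k_d_lipid, self.k_ad_ref, self.k_d_ref) <= 0:
            raise ValueError("all rate coefficients must be strictly positive")


def exchange_constant_from_rates(rates: RateCoefficients) -> float:
    """Exchange constant as the ratio of adsorption/desorption quotients."""
    return (rates.k_ad_lipid / rates.k_d_lipid) / (rates.k_ad_ref / rates.k_d_ref)


def surface_coverage(x_lipid, params: ExchangeParams):
    """Fractional coverage of the transmembrane surface by lipid.

    Accepts a scalar or array mole fraction in [0, 1]; strictly increasing
    with endpoints theta(0) = 0 and theta(1) = 1.
    """
    x = np.asarray(x_lipid, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("mole fraction must lie in [0, 1]")
    num = params.k_ex * (x ** params.beta if params.variant == "symmetric" else x)
    theta = num / ((1 - x) ** params.beta + num)
    return theta if theta.ndim else float(theta)


def composition_for_coverage(
    theta, params: ExchangeParams, tol: float = 1e-12
) -> float:
    """Invert the isotherm: the unique x in [0, 1] with coverage theta.

    For the default form with beta = 2 the inverse is the root of
    theta*x**2 - (2*theta + k_ex*(1-theta))*x + theta = 0 lying in [0, 1];
    other stoichiometries (and the symmetric variant) are solved by
    bracketed bisection to ``tol``.
    """
    if not 0 <= theta <= 1:
        raise ValueError("coverage must lie in [0, 1]")
    if theta == 0.0:
        return 0.0
    if theta == 1.0:
        return 1.0
    if params.variant == "single" and params.beta == 2:
        a, b, c = theta, -(2 * theta + params.k_ex * (1 - theta)), theta
        disc = b * b - 4 * a * c
        root = (-b - np.sqrt(disc)) / (2 * a)  # smaller root lies in [0,1]
        return float(root)
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if surface_coverage(mid, params) < theta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def competitive_coverage(
    composition: MicellarComposition, params: ExchangeParams
) -> tuple[float, float]:
    """Coverage by probe and by unlabeled lipid under equal-affinity competition.

    The labeled probe and the unlabeled lipid are both phosphatidylcholines
    and share one exchange constant; with x_D = 1 - x_lipid - x_probe,

        theta_probe = K_ex*x_probe / (x_D**beta + K_ex*(x_probe + x_lipid))

    and theta_lipid analogously. Returns ``(theta_probe, theta_lipid)``.
    """
    xl, xp = composition.x_lipid, composition.x_probe
    xd = 1.0 - xl - xp
    denom = xd ** params.beta + params.k_ex * (xp + xl)
    if denom == 0:
        # no detergent and no lipid: composition invariants exclude this
        raise ValueError("degenerate composition")
    return params.k_ex * xp / denom, params.k_ex * xl / denom
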