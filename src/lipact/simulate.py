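"""Synthetic titration data with the error structure the analysis assumes.

The generator reproduces the two experimental designs the models were
built for: activity titrations at fixed detergent (1.20/2.75/7.50 mM,
phospholipid varied) and at fixed phospholipid (0.06/0.22/0.53 mM,
detergent varied), and a probe-displacement FRET design (unlabeled lipid
fractions 0.34-0.48, labeled probe titrated). Observations are exact
model means plus homoscedastic Gaussian noise; default standard
deviations are 0.5 umol Pi/mg/min for activity (~4% of the activation
range) and 0.02 for transfer efficiency. Draws that would violate the
physical bounds (negative activity, efficiency outside [0, 1)) are
resampled rather than clipped, keeping the noise unbiased away from the
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import TwoStageParams, activity_from_composition
from .composition import (
    ActivityObservation,
    AmphiphileTotals,
    FretObservation,
    MicellarComposition,
)
from .fret import FretParams, predicted_efficiency

FIXED_DETERGENT_LEVELS_MM = (1.20, 2.75, 7.50)
FIXED_LIPID_LEVELS_MM = (0.06, 0.22, 0.53)
FRET_LIPID_FRACTIONS = (0.34, 0.36, 0.41, 0.44, 0.48)
FRET_PROBE_GRID = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class ActivityDesign:
    """Titration plan: one amphiphile fixed per level, the other varied.

    ``varied_grids`` holds one concentration grid (mM) per fixed level.
    """

    mode: str  # "fixed_detergent" or "fixed_lipid"
    fixed_levels: tuple
    varied_grids: tuple
    replicates: int = 2

    def __post_init__(self):
        if self.mode not in ("fixed_detergent", "fixed_lipid"):
            raise ValueError("mode must be 'fixed_detergent' or 'fixed_lipid'")
        if len(self.varied_grids) != len(self.fixed_levels):
            raise ValueError("one varied grid per fixed level")
        for g in self.varied_grids:
            arr = np.asarray(g, dtype=float)
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError("grids must be strictly positive and sorted")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def totals(self) -> list[AmphiphileTotals]:
        out = []
        for level, grid in zip(self.fixed_levels, self.varied_grids):
            for v in grid:
                if self.mode == "fixed_detergent":
                    out.append(AmphiphileTotals(lipid_conc=v, detergent_conc=level))
                else:
                    out.append(AmphiphileTotals(lipid_conc=level, detergent_conc=v))
        return out


@dataclass(frozen=True)
class FretDesign:
    """Probe-displacement plan: probe titrated at each unlabeled fraction."""

    lipid_fractions: tuple = FRET_LIPID_FRACTIONS
    probe_grid: tuple = FRET_PROBE_GRID
    replicates: int = 1

    def __post_init__(self):
        fr = np.asarray(self.lipid_fractions + self.probe_grid, dtype=float)
        if np.any(fr <= 0) or np.any(fr >= 1):
            raise ValueError("fractions must lie in (0, 1)")
        if max(self.lipid_fractions) + max(self.probe_grid) >= 1:
            raise ValueError("micelles must retain some detergent")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def compositions(self) -> list[MicellarComposition]:
        return [
            MicellarComposition(x_lipid=xl, x_probe=xp)
            for xl in self.lipid_fractions
            for xp in self.probe_grid
        ]


@dataclass(frozen=True)
class NoiseSpec:
    """Homoscedastic Gaussian noise levels and the RNG seed."""

    sd_activity: float = 0.5
    sd_fret: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sd_activity < 0 or self.sd_fret < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _mole_fraction_grid(n: int = 12, x_lo: float = 0.01, x_hi: float = 0.6):
    return np.geomspace(x_lo, x_hi, n)


def paper_activity_design(
    points_per_level: int = 12, replicates: int = 2
) -> tuple[ActivityDesign, ActivityDesign]:
    """The two activity titration designs at their published fixed levels.

    Design A holds detergent at 1.20/2.75/7.50 mM and titrates lipid over
    a log-spaced grid spanning mole fractions ~0.01-0.6; design B holds
    lipid at 0.06/0.22/0.53 mM and titrates detergent so the mole
    fraction spans ~0.02-0.5.
    """
    xa = _mole_fraction_grid(points_per_level, 0.01, 0.6)
    design_a = ActivityDesign(
        mode="fixed_detergent",
        fixed_levels=FIXED_DETERGENT_LEVELS_MM,
        varied_grids=tuple(
            tuple(d * xa / (1 - xa)) for d in FIXED_DETERGENT_LEVELS_MM
        ),
        replicates=replicates,
    )
    xb = _mole_fraction_grid(points_per_level, 0.02, 0.5)
    design_b = ActivityDesign(
        mode="fixed_lipid",
        fixed_levels=FIXED_LIPID_LEVELS_MM,
        varied_grids=tuple(
            # detergent grid sorted ascending = mole fraction descending
            tuple(sorted(lp * (1 - xb) / xb)) for lp in FIXED_LIPID_LEVELS_MM
        ),
        replicates=replicates,
    )
    return design_a, design_b


def paper_fret_design(replicates: int = 1) -> FretDesign:
    """The probe-displacement design at the published lipid fractions."""
    return FretDesign(replicates=replicates)


def _truncated_normal(rng, mean, sd, lo, hi):
    """Gaussian draw resampled into (lo, hi); unbiased away from bounds."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi - 1e-12))


def simulate_activity(
    truth: TwoStageParams,
    design: ActivityDesign | tuple,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> list[ActivityObservation]:
    """Draw activity observations: model mean plus Gaussian noise.

    ``design`` may be a single :class:`ActivityDesign` or a tuple of them
    (e.g. the pair from :func:`paper_activity_design`). With sd 0 the
    observations lie exactly on the model curve.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    designs = design if isinstance(design, tuple) else (design,)
    out = []
    for d in designs:
        for totals in d.totals():
            x = totals.lipid_conc / (totals.lipid_conc + totals.detergent_conc)
            mean = activity_from_composition(x, truth)
            for _ in range(d.replicates):
                a = _truncated_normal(rng, mean, noise.sd_activity, 0.0, np.inf)
                out.append(ActivityObservation(totals=totals, activity=a))
    return out


def simulate_fret(
    truth: FretParams,
    design: FretDesign,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> list[FretObservation]:
    """Draw apparent-efficiency observations, truncated to [0, 1)."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    out = []
    for comp in design.compositions():
        mean = predicted_efficiency(comp, truth)
        for _ in range(design.replicates):
            e = _truncated_normal(rng, mean, noise.sd_fret, 0.0, 1.0)
            out.append(FretObservation(composition=comp, e_app=e))
    return out


def intensity_pairs(observations: list[FretObservation]):
    """Optional raw-intensity view of FRET data (i_d = 1, i_da = 1 - e)."""
    from .fret import DonorIntensities

    return [DonorIntensities(i_d=1.0, i_da=1.0 - o.e_app) for o in observations]
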