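"""Titration records and micellar-composition arithmetic.

All amphiphile concentrations are total concentrations in mM. Because the
critical micellar concentrations of the species of interest (~0.5 nM for
DPPC, ~5 uM for C12E10) are orders of magnitude below working mM
concentrations, both species are treated as fully micellar by default and
the micellar mole fraction is simply lipid/(lipid+detergent). An optional
per-species CMC subtraction is available for solvents where monomers are
not negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


class ParseError(ValueError):
    """A delimited-text table failed validation; message names the row."""


@dataclass(frozen=True)
class AmphiphileTotals:
    """Total lipid and detergent concentrations in a sample (mM)."""

    lipid_conc: float
    detergent_conc: float

    def __post_init__(self):
        if self.lipid_conc < 0 or self.detergent_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.lipid_conc + self.detergent_conc <= 0:
            raise ValueError("at least one amphiphile must be present")


@dataclass(frozen=True)
class MicellarComposition:
    """Mole fractions of lipid species in the micellar phase.

    ``x_lipid`` is the unlabeled phospholipid mole fraction; ``x_probe``
    the labeled-probe fraction (zero outside FRET experiments). The
    remainder, 1 - x_lipid - x_probe, is detergent.
    """

    x_lipid: float
    x_probe: float = 0.0

    def __post_init__(self):
        if self.x_lipid < 0 or self.x_probe < 0:
            raise ValueError("mole fractions must be non-negative")
        if self.x_lipid + self.x_probe > 1 + 1e-12:
            raise ValueError("mole fractions must sum to at most 1")


@dataclass(frozen=True)
class ActivityObservation:
    """One ATPase-activity measurement (umol Pi / mg protein / min)."""

    totals: AmphiphileTotals
    activity: float

    def __post_init__(self):
        if self.activity < 0:
            raise ValueError("activity must be non-negative")


@dataclass(frozen=True)
class FretObservation:
    """One apparent-transfer-efficiency measurement."""

    composition: MicellarComposition
    e_app: float

    def __post_init__(self):
        if not 0 <= self.e_app < 1:
            raise ValueError("e_app must lie in [0, 1)")


def micellar_mole_fraction(
    totals: AmphiphileTotals,
    cmc_lipid: float = 0.0,
    cmc_detergent: float = 0.0,
) -> MicellarComposition:
    """Convert total concentrations to the lipid mole fraction in micelles.

    CMCs default to zero (monomers neglected); when given, the monomeric
    pool is subtracted from each total, floored at zero.
    """
    lipid = max(totals.lipid_conc - cmc_lipid, 0.0)
    detergent = max(totals.detergent_conc - cmc_detergent, 0.0)
    if lipid + detergent <= 0:
        raise ValueError("no micellar amphiphile after CMC subtraction")
    return MicellarComposition(x_lipid=lipid / (lipid + detergent))


_ACTIVITY_COLS = ["detergent_mM", "lipid_mM", "activity"]
_FRET_COLS = ["x_lipid", "x_probe", "e_app"]


def _read_table(path, columns, sep=","):
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        vals = []
        for c in columns:
            v = row[c]
            if not isinstance(v, (int, float)) or (
                isinstance(v, float) and math.isnan(v)
            ):
                raise ParseError(f"row {i + 1}: non-numeric value in '{c}'")
            vals.append(float(v))
        records.append((i + 1, vals))
    return records


def read_activity_table(path, sep: str = ",") -> list[ActivityObservation]:
    """Read activity observations from delimited text.

    Expects one header line with columns ``detergent_mM``, ``lipid_mM``,
    ``activity``; raises :class:`ParseError` naming the offending row on
    any missing column, non-numeric cell or invariant violation.
    """
    out = []
    for rownum, (det, lip, act) in _read_table(path, _ACTIVITY_COLS, sep):
        try:
            out.append(ActivityObservation(AmphiphileTotals(lip, det), act))
        except ValueError as exc:
            raise ParseError(f"row {rownum}: {exc}") from exc
    return out


def write_activity_table(path, observations, sep: str = ","):
    pd.DataFrame(
        [
            {
                "detergent_mM": o.totals.detergent_conc,
                "lipid_mM": o.totals.lipid_conc,
                "activity": o.activity,
            }
            for o in observations
        ],
        columns=_ACTIVITY_COLS,
    ).to_csv(path, sep=sep, index=False)


def read_fret_table(path, sep: str = ",") -> list[FretObservation]:
    """Read FRET observations (columns x_lipid, x_probe, e_app)."""
    out = []
    for rownum, (xl, xp, e) in _read_table(path, _FRET_COLS, sep):
        try:
            out.append(FretObservation(MicellarComposition(xl, xp), e))
        except ValueError as exc:
            raise ParseError(f"row {rownum}: {exc}") from exc
    return out


def write_fret_table(path, observations, sep: str = ","):
    pd.DataFrame(
        [
            {
                "x_lipid": o.composition.x_lipid,
                "x_probe": o.composition.x_probe,
                "e_app": o.e_app,
            }
            for o in observations
        ],
        columns=_FRET_COLS,
    ).to_csv(path, sep=sep, index=False)


@dataclass
class CompositionGroup:
    """Activity observations sharing (within tolerance) one mole fraction."""

    x_lipid: float
    observations: list = field(default_factory=list)

    @property
    def mean_activity(self) -> float:
        acts = [o.activity for o in self.observations]
        return sum(acts) / len(acts)

    @property
    def activity_sd(self) -> float:
        acts = [o.activity for o in self.observations]
        if len(acts) < 2:
            return 0.0
        m = sum(acts) / len(acts)
        return math.sqrt(sum((a - m) ** 2 for a in acts) / (len(acts) - 1))


def collapse_by_composition(
    observations: list[ActivityObservation], tolerance: float = 1e-6
) -> list[CompositionGroup]:
    """Group observations by micellar mole fraction.

    Observations whose mole fractions differ by less than ``tolerance``
    share a group; this realizes the collapse of titrations performed at
    different total concentrations onto a single composition axis.
    """
    tagged = sorted(
        ((micellar_mole_fraction(o.totals).x_lipid, o) for o in observations),
        key=lambda t: t[0],
    )
    groups: list[CompositionGroup] = []
    for x, obs in tagged:
        if groups and abs(x - groups[-1].x_lipid) < tolerance:
            groups[-1].observations.append(obs)
        else:
            groups.append(CompositionGroup(x_lipid=x, observations=[obs]))
    return groups
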