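"""Observation model for the probe-displacement FRET assay.

A pyrene-labeled phosphatidylcholine (acceptor) quenches the protein's
tryptophan fluorescence (donor) when it occupies the transmembrane
surface. Unlabeled phospholipid competes it off, so the apparent transfer
efficiency falls as the unlabeled fraction rises — which is what makes the
assay report the exchange constant. The efficiency is coupled to the
probe's surface coverage theta_H through a saturating law

    E_app = xi * theta_H / (1 + xi * theta_H)

with xi a protein/probe coupling parameter; E_app is bounded in [0, 1) for
any coverage, as a physical efficiency must be.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import MicellarComposition
from .exchange import ExchangeParams, competitive_coverage


@dataclass(frozen=True)
class FretParams:
    """Probe coupling parameter plus the (shared) exchange parameters."""

    xi: float
    exchange: ExchangeParams

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("xi must be positive")


@dataclass(frozen=True)
class DonorIntensities:
    """Donor (Trp) intensity without and with acceptor, background-subtracted."""

    i_d: float
    i_da: float

    def __post_init__(self):
        if self.i_d <= 0 or self.i_da <= 0:
            raise ValueError("intensities must be positive")
        if self.i_da > self.i_d:
            raise ValueError("acceptor can only quench: require i_da <= i_d")


def apparent_efficiency(intensities: DonorIntensities) -> float:
    """E_app = 1 - I_da / I_d."""
    return 1.0 - intensities.i_da / intensities.i_d


def predicted_efficiency(
    composition: MicellarComposition, p: FretParams
) -> float:
    """Model E_app for a micellar composition containing the labeled probe.

    Strictly increasing in the probe fraction and zero iff no probe is
    present. At fixed probe, raising the unlabeled fraction displaces the
    probe (efficiency falls) throughout the assay's lipid-rich window;
    below it (2 * x_detergent > K_ex) added lipid mainly competes with
    detergent and probe coverage can still rise.
    """
    if composition.x_lipid + composition.x_probe >= 1:
        raise ValueError("micelles must retain some detergent")
    theta_probe, _ = competitive_coverage(composition, p.exchange)
    z = p.xi * theta_probe
    return z / (1.0 + z)
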