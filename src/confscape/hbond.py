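"""Additive intramolecular hydrogen-bond strength model.

Conformer energy differences in gas-phase amino acids can be rationalized, to
roughly +-100-200 cm^-1, as sums of near-atom interaction strengths:
donors rank O-H > N-H > S-H and acceptors N > O > S, so the amine-accepting
OH...N bond (3200 cm^-1) is the strongest, followed by amide-type NH2...HNH
(2400), the bifurcated NH2...O=C (1700) and NH2...OH (1100) contacts, their
single-contact HNH...O=C (1300) and HNH...OH (800) variants, and the
sulfur-involving contacts (~800).  A trans carboxylic arrangement
(omega = 180 deg) is worth ~1700 cm^-1 over cis.

These are qualitative estimates: they explain stability orders, they are
never fed back into the quantitative free-energy pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "DEFAULT_STRENGTHS",
    "CARBOXYL_TRANS_PREFERENCE",
    "HBInventory",
    "stabilization_score",
    "predict_gap",
]

#: Interaction strengths in cm^-1.
DEFAULT_STRENGTHS: dict[str, float] = {
    "OH...N": 3200.0,          # backbone carboxylic O-H donating to the amine N
    "NH2...HNH": 2400.0,       # amide N accepting from an amine N-H
    "NH2...O=C": 1700.0,       # bifurcated amine to carbonyl (type I)
    "HNH...O=C": 1300.0,       # single amine N-H to carbonyl (type I')
    "NH2...OH": 1100.0,        # bifurcated amine to hydroxyl (type III)
    "HNH...OH": 800.0,         # single amine N-H to hydroxyl (type III')
    "OH...O=C": 800.0,         # side-chain hydroxyl to backbone carbonyl
    "H2N...HS": 800.0,         # thiol donating to the amine
    "HS...HNH": 800.0,         # thiol accepting from the amine
    "SH...O=C": 800.0,         # thiol donating to the carbonyl
}

#: Extra stabilization of a trans (omega = 180 deg) carboxylic group over cis.
CARBOXYL_TRANS_PREFERENCE = 1700.0


@dataclass(frozen=True)
class HBInventory:
    """Declared hydrogen-bond contacts of one conformer plus the number of
    carboxyl groups in the favourable trans arrangement."""

    interactions: tuple = ()
    n_trans_carboxyl: int = 0

    def __post_init__(self):
        if self.n_trans_carboxyl < 0:
            raise ValueError("carboxyl count must be >= 0")


def stabilization_score(
    inventory: HBInventory,
    strengths: Mapping[str, float] = DEFAULT_STRENGTHS,
    carboxyl_preference: float = CARBOXYL_TRANS_PREFERENCE,
) -> float:
    """Total stabilization (cm^-1): sum of contact strengths plus the trans-
    carboxyl preference for each flagged carboxyl group."""
    total = 0.0
    for name in inventory.interactions:
        if name not in strengths:
            raise KeyError(
                f"unknown interaction {name!r}; known: {sorted(strengths)}"
            )
        total += strengths[name]
    return total + inventory.n_trans_carboxyl * carboxyl_preference


def predict_gap(
    inventory_a: HBInventory,
    inventory_b: HBInventory,
    strengths: Mapping[str, float] = DEFAULT_STRENGTHS,
    carboxyl_preference: float = CARBOXYL_TRANS_PREFERENCE,
) -> float:
    """Predicted relative energy of A with respect to B (cm^-1).

    score(B) - score(A): positive means A lies above B (B better stabilized);
    negative means A is the more stable conformer.
    """
    return stabilization_score(inventory_b, strengths, carboxyl_preference) - (
        stabilization_score(inventory_a, strengths, carboxyl_preference)
    )
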