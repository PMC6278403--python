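"""Monoisotopic peptide masses, charged m/z values, and charge inference.

All masses are monoisotopic.  Reported values are rounded half away from
zero to 2 decimals; internal computation keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from ._util import AMINO_ACIDS, round_half_away

WATER = 18.010565          # Da, monoisotopic H2O
PROTON = 1.007276          # Da, monoisotopic H+
C13_C12 = 1.0033548        # Da, 13C - 12C mass difference

#: Monoisotopic residue masses (peptide-bonded residues, Da).
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
})

assert set(RESIDUE_MASSES) == AMINO_ACIDS


@dataclass(frozen=True)
class PeptideIon:
    """A protonated peptide at charge z; mz = (M + z * proton) / z."""

    sequence: str
    charge: int
    mz: float


def monoisotopic_mass(sequence: str, modifications: Mapping[str, float] | None = None) -> float:
    """Neutral monoisotopic mass: sum of residue masses plus one water.

    ``modifications`` optionally maps residue letters to fixed mass deltas
    (e.g. carbamidomethyl-C +57.02146, oxidised-M +15.994915); off by default.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    mods = modifications or {}
    total = WATER
    for i, ch in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[ch]
        except KeyError:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} in {sequence!r}"
            ) from None
        total += mods.get(ch, 0.0)
    return total


def mz(mass: float, z: int) -> float:
    """m/z of the z-fold protonated ion: (mass + z * proton) / z."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def peptide_ion(sequence: str, z: int,
                modifications: Mapping[str, float] | None = None) -> PeptideIon:
    return PeptideIon(sequence=sequence, charge=z,
                      mz=mz(monoisotopic_mass(sequence, modifications), z))


def isotope_spacing(z: int) -> float:
    """m/z spacing of adjacent isotope peaks at charge z: (13C-12C)/z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return C13_C12 / z


def infer_charge(observed_spacing: float, max_z: int = 6,
                 tolerance: float = 0.1) -> int | None:
    """Charge state whose theoretical isotope spacing best matches the data.

    Ties break toward the smaller charge; returns None ("no call") when the
    best residual exceeds ``tolerance``.
    """
    if observed_spacing <= 0:
        raise ValueError(f"spacing must be positive, got {observed_spacing}")
    best_z = min(range(1, max_z + 1),
                 key=lambda z: (abs(observed_spacing - isotope_spacing(z)), z))
    if abs(observed_spacing - isotope_spacing(best_z)) > tolerance:
        return None
    return best_z


def format_mass(value: float) -> str:
    """Render a mass or m/z value to 2 decimals, halves away from zero."""
    return f"{round_half_away(value, 2):.2f}"
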