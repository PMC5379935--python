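"""Crystallographic bookkeeping.

Triclinic cell volume, the Matthews coefficient V_M = V_cell/(Z·M) with
its solvent fraction 1 − 1.23/V_M (1.23 Å³ Da⁻¹ from a partial specific
volume of 0.74 cm³ g⁻¹), average/monoisotopic protein mass from a
one-letter sequence, and the data-to-parameter (reflections-per-atom)
ratio used when choosing a B-factor model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import UnitCell

__all__ = [
    "MatthewsResult",
    "cell_volume",
    "matthews",
    "protein_mass",
    "reflections_per_atom",
    "AVERAGE_RESIDUE_MASS",
    "MONO_RESIDUE_MASS",
    "WATER_AVERAGE",
    "WATER_MONO",
]

#: Å³ Da⁻¹, from protein partial specific volume 0.74 cm³/g
SOLVENT_CONSTANT = 1.23

# average residue (amino-acid minus water) masses, Da
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.0153
WATER_MONO = 18.010565


@dataclass
class MatthewsResult:
    cell_volume: float  # Å³
    z: int
    mass: float  # Da
    v_m: float  # Å³/Da
    solvent_fraction: float  # 0–1


def cell_volume(cell: UnitCell) -> float:
    """Triclinic cell volume
    V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ)."""
    ca, cb, cg = (np.cos(np.deg2rad(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise ValueError("invalid cell: non-positive volume discriminant")
    return float(cell.a * cell.b * cell.c * np.sqrt(disc))


def matthews(cell: UnitCell, z: int, mass: float) -> MatthewsResult:
    """Matthews coefficient and solvent content for Z copies of ``mass``
    Da in the cell."""
    if z < 1:
        raise ValueError("z must be ≥ 1")
    if mass <= 0:
        raise ValueError("mass must be positive")
    vol = cell_volume(cell)
    v_m = vol / (z * mass)
    if v_m < 1.0:
        warnings.warn(f"V_M = {v_m:.2f} Å³/Da is implausibly low", UserWarning, stacklevel=2)
    solvent = min(max(1.0 - SOLVENT_CONSTANT / v_m, 0.0), 1.0)
    return MatthewsResult(cell_volume=vol, z=z, mass=mass, v_m=v_m, solvent_fraction=solvent)


def protein_mass(sequence: str, kind: str = "average") -> float:
    """Mass (Da) of a polypeptide from its one-letter sequence: residue
    masses plus one water."""
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    if kind == "average":
        table, water = AVERAGE_RESIDUE_MASS, WATER_AVERAGE
    elif kind == "monoisotopic":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    try:
        return sum(table[c] for c in seq) + water
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid letter {exc.args[0]!r}") from None


def reflections_per_atom(n_unique_reflections: int, n_atoms: int) -> float:
    """Data-to-parameter ratio, reported to one decimal."""
    if n_unique_reflections <= 0 or n_atoms <= 0:
        raise ValueError("counts must be positive")
    return round(n_unique_reflections / n_atoms, 1)
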