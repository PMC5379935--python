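"""Solvent-accessible and buried surface area.

Shrake–Rupley surface-dot counting: each atom is covered with a
deterministic golden-spiral point set on a sphere of radius
r_vdw + probe; the accessible area is the exposed-dot fraction times
the sphere area.  Dot placement is deterministic (not random) so that
every run is exactly reproducible.

Buried surface area between two parts A and B of a complex is
BSA = ASA_A + ASA_B − ASA_AB on identical atom sets.  The consensus of
several independent surface programs is emulated by an ensemble over
dot densities of this single algorithm, reported as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Selection, StructureModel

__all__ = [
    "SasaResult",
    "BsaResult",
    "VDW_RADII",
    "DEFAULT_ENSEMBLE",
    "shrake_rupley",
    "buried_surface_area",
    "sphere_dots",
]

#: element-based van der Waals radii, Å (Bondi-style); elements known to
#: the periodic table but absent here fall back to 1.70 Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 1.94, "MN": 1.97, "CO": 1.92, "NI": 1.84, "CU": 1.86,
}
FALLBACK_RADIUS = 1.70

DEFAULT_PROBE = 1.4
#: ensemble of (probe radius, dot count) settings emulating a multi-method consensus
DEFAULT_ENSEMBLE = tuple((DEFAULT_PROBE, n) for n in (320, 640, 960, 1280, 1920))

_KNOWN_ELEMENTS = set(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI CU ZN "
    "GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I XE CS BA W PT AU HG PB U D".split()
)


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with model atom order
    total: float  # Å²
    probe_radius: float
    n_dots: int


@dataclass
class BsaResult:
    asa_a: float
    asa_b: float
    asa_ab: float
    bsa: float
    ensemble_mean: float
    ensemble_sd: float
    ensemble_settings: list
    ensemble_values: list


def sphere_dots(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) point set on the unit sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_radius(element: str, atom_label: str = "") -> float:
    el = element.strip().upper()
    if not el or el not in _KNOWN_ELEMENTS:
        raise ValueError(f"no van der Waals radius for element {element!r}"
                         + (f" (atom {atom_label})" if atom_label else ""))
    return VDW_RADII.get(el, FALLBACK_RADIUS)


def shrake_rupley(model: StructureModel, probe_radius: float = DEFAULT_PROBE,
                  n_dots: int = 960, radii_set: str = "default") -> SasaResult:
    """Per-atom solvent-accessible surface by surface-dot counting.

    area_i = (exposed dots / n_dots) · 4π (r_i + probe)², a dot being
    exposed when it lies outside every neighbouring solvent-expanded
    sphere.
    """
    if radii_set != "default":
        raise ValueError(f"unknown radii set {radii_set!r}")
    if n_dots < 92:
        raise ValueError("n_dots must be ≥ 92 for a usable quadrature")
    if len(model) == 0:
        return SasaResult(per_atom=np.zeros(0), total=0.0, probe_radius=probe_radius, n_dots=n_dots)
    coords = model.coords()
    radii = np.array([atom_radius(a.element, f"{a.chain_id}/{a.res_seq}/{a.name}") for a in model])
    expanded = radii + probe_radius
    unit = sphere_dots(n_dots)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, expanded)):
        dots = c + r * unit
        exposed = np.ones(n_dots, dtype=bool)
        for j in tree.query_ball_point(c, r + expanded.max()):
            if j == i:
                continue
            rj = expanded[j]
            if np.linalg.norm(coords[j] - c) >= r + rj:
                continue
            exposed &= np.sum((dots - coords[j]) ** 2, axis=1) > rj * rj
            if not exposed.any():
                break
        per_atom[i] = exposed.sum() / n_dots * 4.0 * np.pi * r * r
    return SasaResult(per_atom=per_atom, total=float(per_atom.sum()),
                      probe_radius=probe_radius, n_dots=n_dots)


def _submodel(model: StructureModel, keys: set) -> StructureModel:
    atoms = [a.copy() for a in model.atoms if a.key in keys]
    return StructureModel(atoms=atoms, cell=model.cell, title=model.title)


def buried_surface_area(complex_model: StructureModel, part_a: Selection, part_b: Selection,
                        ensemble: list | tuple = DEFAULT_ENSEMBLE,
                        include_het: bool = False) -> BsaResult:
    """Interface area between two parts of a complex.

    Heteroatoms are excluded by default (the ring–ring interface is
    protein-defined; lattice solvent/ions are not part of it).  The two
    selections must not overlap.  Each ensemble (probe, n_dots) setting
    yields one BSA value; the headline numbers are their mean and SD,
    with the first setting's components reported individually.
    """
    if not ensemble:
        raise ValueError("ensemble must be nonempty")
    keys_a = {a.key for a in complex_model.atoms
              if part_a.matches(a) and (include_het or not a.is_het)}
    keys_b = {a.key for a in complex_model.atoms
              if part_b.matches(a) and (include_het or not a.is_het)}
    if keys_a & keys_b:
        raise ValueError("part_a and part_b overlap")
    if not keys_a or not keys_b:
        raise ValueError("both parts must select at least one atom")
    model_a = _submodel(complex_model, keys_a)
    model_b = _submodel(complex_model, keys_b)
    model_ab = _submodel(complex_model, keys_a | keys_b)

    values = []
    first = None
    for probe, n_dots in ensemble:
        asa_a = shrake_rupley(model_a, probe, n_dots).total
        asa_b = shrake_rupley(model_b, probe, n_dots).total
        asa_ab = shrake_rupley(model_ab, probe, n_dots).total
        bsa = asa_a + asa_b - asa_ab
        values.append(bsa)
        if first is None:
            first = (asa_a, asa_b, asa_ab, bsa)
    values_arr = np.array(values)
    return BsaResult(
        asa_a=first[0], asa_b=first[1], asa_ab=first[2], bsa=first[3],
        ensemble_mean=float(values_arr.mean()),
        ensemble_sd=float(values_arr.std(ddof=1)) if len(values) > 1 else 0.0,
        ensemble_settings=list(ensemble),
        ensemble_values=[float(v) for v in values],
    )
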