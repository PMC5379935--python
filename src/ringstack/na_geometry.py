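"""Nucleotide conformation and contact analysis.

Covers the standard descriptors of ribonucleotide geometry — signed
torsion angles, the glycosidic angle χ with its syn/anti class, and the
furanose pseudorotation phase P and amplitude ν_max with the 18°-bin
pucker nomenclature (C3'-endo near P = 18°, C2'-endo near 162°) — plus
distance-based protein⋯RNA contact tables and a π-stacking test.

Hydrogen-bond candidates are detected from heavy-atom distance and
element only (N/O pairs within 3.5 Å): deposited structures carry no
hydrogens, so no angular term is applied.  This is a heuristic, not an
energy model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Selection, StructureModel

__all__ = [
    "PuckerResult",
    "ChiResult",
    "ContactRecord",
    "dihedral",
    "glycosidic_chi",
    "pseudorotation",
    "contact_table",
    "stacking_check",
    "residue_view",
]

# 20 pseudorotation bins of 18°, bin k centred at P = 18°·k
PUCKER_BINS = (
    "C3'-endo/C2'-exo twist", "C3'-endo", "C3'-endo/C4'-exo twist", "C4'-exo",
    "O4'-endo/C4'-exo twist", "O4'-endo", "O4'-endo/C1'-exo twist", "C1'-exo",
    "C2'-endo/C1'-exo twist", "C2'-endo", "C2'-endo/C3'-exo twist", "C3'-exo",
    "C4'-endo/C3'-exo twist", "C4'-endo", "O4'-exo/C4'-endo twist", "O4'-exo",
    "C1'-endo/O4'-exo twist", "C1'-endo", "C2'-exo/C1'-endo twist", "C2'-exo",
)

FURANOSE_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

_TORSION_QUADS = (
    ("C4'", "O4'", "C1'", "C2'"),  # ν0
    ("O4'", "C1'", "C2'", "C3'"),  # ν1
    ("C1'", "C2'", "C3'", "C4'"),  # ν2
    ("C2'", "C3'", "C4'", "O4'"),  # ν3
    ("C3'", "C4'", "O4'", "C1'"),  # ν4
)

PURINES = {"A", "G", "DA", "DG", "ADE", "GUA"}
PYRIMIDINES = {"U", "C", "T", "DU", "DC", "DT", "URA", "CYT", "THY"}


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (IUPAC convention) in (−180°, 180°]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise ValueError("degenerate torsion: middle bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate torsion: collinear atoms")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = np.rad2deg(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def residue_view(model: StructureModel, chain_id: str | None = None,
                 res_seq: int | None = None) -> dict[str, np.ndarray]:
    """Atom-name → coordinate map for one residue.

    With no chain/residue given the model must contain exactly one residue.
    """
    if chain_id is None and res_seq is None:
        residues = model.residues()
        if len(residues) != 1:
            raise ValueError("model holds several residues; specify chain_id/res_seq")
        atoms = residues[0][4]
    else:
        atoms = [a for a in model.atoms
                 if (chain_id is None or a.chain_id == chain_id)
                 and (res_seq is None or a.res_seq == res_seq)]
        if not atoms:
            raise ValueError(f"residue {chain_id}/{res_seq} not found")
    return {a.name: a.xyz for a in atoms} | {"__res_name__": atoms[0].res_name}


@dataclass
class ChiResult:
    chi: float  # degrees in (−180°, 180°]
    conformer: str  # 'syn' | 'anti'
    quad: tuple


@dataclass
class PuckerResult:
    nu: tuple  # ν0..ν4, degrees
    P: float  # phase, [0°, 360°)
    nu_max: float  # amplitude, degrees
    pucker_class: str | None
    hemisphere: str | None
    amplitude_undefined: bool = False


def glycosidic_chi(nucleotide) -> ChiResult:
    """Glycosidic torsion χ (O4'–C1'–N1–C2 for pyrimidines, O4'–C1'–N9–C4
    for purines) and its syn/anti class (anti iff |χ| ≥ 90°)."""
    view = nucleotide if isinstance(nucleotide, dict) else residue_view(nucleotide)
    res_name = view.get("__res_name__", "")
    if res_name in PURINES or ("N9" in view and "C4" in view and "N1" not in view):
        quad = ("O4'", "C1'", "N9", "C4")
    else:
        quad = ("O4'", "C1'", "N1", "C2")
    missing = [n for n in quad if n not in view]
    if missing:
        raise ValueError(f"glycosidic torsion atoms missing: {', '.join(missing)}")
    chi = dihedral(*(view[n] for n in quad))
    return ChiResult(chi=chi, conformer="anti" if abs(chi) >= 90.0 else "syn", quad=quad)


def pseudorotation(nucleotide) -> PuckerResult:
    """Furanose pseudorotation phase and amplitude.

    Uses tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°)) with
    ν2 = ν_max·cos P, so C3'-endo sits near P = 18° and C2'-endo near
    162°.  Near-planar rings (ν_max < 5°) get no pucker class.
    """
    view = nucleotide if isinstance(nucleotide, dict) else residue_view(nucleotide)
    missing = [n for n in FURANOSE_ATOMS if n not in view]
    if missing:
        raise ValueError(f"furanose atoms missing: {', '.join(missing)}")
    nu = tuple(dihedral(*(view[n] for n in quad)) for quad in _TORSION_QUADS)
    denom = 2.0 * nu[2] * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))
    P = np.rad2deg(np.arctan2((nu[4] + nu[1]) - (nu[3] + nu[0]), denom))
    if nu[2] < 0:
        # arctan2 already handles the quadrant via the signed denominator
        pass
    P %= 360.0
    nu_max = abs(nu[2] / np.cos(np.deg2rad(P))) if abs(np.cos(np.deg2rad(P))) > 1e-6 else abs(
        ((nu[4] + nu[1]) - (nu[3] + nu[0])) / (2.0 * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0))))
    )
    if nu_max < 5.0:
        return PuckerResult(nu=nu, P=float(P), nu_max=float(nu_max), pucker_class=None,
                            hemisphere=None, amplitude_undefined=True)
    bin_index = int(np.round(P / 18.0)) % 20
    if P < 45.0 or P >= 315.0:
        hemisphere = "North"
    elif P < 135.0:
        hemisphere = "East"
    elif P < 225.0:
        hemisphere = "South"
    else:
        hemisphere = "West"
    return PuckerResult(nu=nu, P=float(P), nu_max=float(nu_max),
                        pucker_class=PUCKER_BINS[bin_index], hemisphere=hemisphere)


@dataclass
class ContactRecord:
    atom_a: tuple  # (chain, res_seq, res_name, atom name)
    atom_b: tuple
    distance: float
    contact_class: str  # 'hbond-candidate' | 'vdw'
    symmetry_note: str = ""


def contact_table(model: StructureModel, group_a: Selection, group_b: Selection,
                  cutoff: float = 3.6) -> list[ContactRecord]:
    """All inter-group atom pairs within ``cutoff`` Å, sorted by distance.

    Pairs with both atoms in {N, O} at ≤ 3.5 Å are labelled
    hbond-candidate, everything else vdw.  Groups must be disjoint.
    """
    atoms_a = [a for a in model.atoms if group_a.matches(a)]
    atoms_b = [a for a in model.atoms if group_b.matches(a)]
    keys_a = {a.key for a in atoms_a}
    if any(b.key in keys_a for b in atoms_b):
        raise ValueError("contact groups must be disjoint")
    if not atoms_a or not atoms_b:
        warnings.warn("empty contact group; returning empty table", UserWarning, stacklevel=2)
        return []
    xa = np.vstack([a.xyz for a in atoms_a])
    xb = np.vstack([b.xyz for b in atoms_b])
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=cutoff)
    records: list[ContactRecord] = []
    for i, hits in enumerate(pairs):
        for j in hits:
            a, b = atoms_a[i], atoms_b[j]
            dist = float(np.linalg.norm(a.xyz - b.xyz))
            if dist <= 0:
                continue
            hb = a.element in ("N", "O") and b.element in ("N", "O") and dist <= 3.5
            records.append(
                ContactRecord(
                    atom_a=(a.chain_id, a.res_seq, a.res_name, a.name),
                    atom_b=(b.chain_id, b.res_seq, b.res_name, b.name),
                    distance=dist,
                    contact_class="hbond-candidate" if hb else "vdw",
                )
            )
    records.sort(key=lambda r: r.distance)
    return records


def stacking_check(ring_a_atoms: np.ndarray, ring_b_atoms: np.ndarray,
                   max_centroid_distance: float = 4.5, max_plane_angle: float = 30.0,
                   max_offset: float = 2.5, planarity_rms: float = 0.3) -> dict:
    """π-stacking test between two planar ring systems.

    ``is_stacked`` requires centroid distance ≤ 4.5 Å, inter-plane angle
    ≤ 30° and in-plane centroid offset ≤ 2.5 Å (defaults; all exposed).
    Rings whose best-fit plane RMS exceeds 0.3 Å are flagged non-planar.
    """
    from .ring_geometry import best_fit_plane

    a = np.asarray(ring_a_atoms, float)
    b = np.asarray(ring_b_atoms, float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each ring needs at least 5 atoms")
    pa = best_fit_plane(a)
    pb = best_fit_plane(b)
    flagged = pa.rms_residual > planarity_rms or pb.rms_residual > planarity_rms
    centroid_vec = pb.centroid - pa.centroid
    centroid_distance = float(np.linalg.norm(centroid_vec))
    cosang = abs(float(np.dot(pa.normal, pb.normal)))
    plane_angle = float(np.rad2deg(np.arccos(np.clip(cosang, 0.0, 1.0))))
    along = float(np.dot(centroid_vec, pa.normal))
    offset = float(np.sqrt(max(centroid_distance**2 - along**2, 0.0)))
    return {
        "centroid_distance": centroid_distance,
        "plane_angle": plane_angle,
        "offset": offset,
        "is_stacked": bool(
            not flagged
            and centroid_distance <= max_centroid_distance
            and plane_angle <= max_plane_angle
            and offset <= max_offset
        ),
        "non_planar_flag": bool(flagged),
    }
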