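"""Generators for synthetic test inputs.

Three families of inputs are produced, matching what the downstream
analyses assume about real data:

* idealized C\ :sub:`n`-symmetric rings and head-to-tail stacked double
  rings with controllable inter-ring rotation Δ, tilt δ, rise and
  Gaussian coordinate noise;
* a single ribonucleoside with a requested furanose pseudorotation
  phase/amplitude and glycosidic torsion χ;
* fluorescence-polarization titrations drawn from either binding model
  with Gaussian read noise and replicates.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .structure_io import AtomRecord, StructureModel, rotation_about_axis
from .binding import FPDataset, eval_logistic4, eval_depletion, Logistic4Params, DepletionParams

__all__ = [
    "RingSpec",
    "StackSpec",
    "FPSimSpec",
    "make_ring",
    "make_stacked_rings",
    "make_sugar_ring",
    "simulate_fp",
    "DEFAULT_TEMPLATE",
]

# Rigid asymmetric 10-point subunit template (Å, centroid at origin).
# Deliberately without any internal symmetry so that superposition and
# clustering tests cannot succeed by accident.
DEFAULT_TEMPLATE: np.ndarray = np.array(
    [
        [2.10, 0.40, -1.10],
        [0.90, 1.80, 0.60],
        [-1.30, 2.20, -0.70],
        [-2.40, 0.10, 1.20],
        [-1.00, -1.90, -1.60],
        [0.70, -2.30, 0.90],
        [2.60, -1.20, 1.70],
        [-0.20, 0.60, 2.40],
        [0.40, -0.50, -2.60],
        [-1.80, 0.80, -0.80],
    ]
)
DEFAULT_TEMPLATE = DEFAULT_TEMPLATE - DEFAULT_TEMPLATE.mean(axis=0)

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class RingSpec:
    """C\ :sub:`n` ring of identical subunits placed at a given radius."""

    n_subunits: int = 6
    radius: float = 22.0
    noise_sigma: float = 0.0
    seed: int = 0
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("a ring needs at least 3 subunits")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def template_coords(self) -> np.ndarray:
        t = DEFAULT_TEMPLATE if self.template is None else np.asarray(self.template, float)
        return t - t.mean(axis=0)


@dataclass(frozen=True)
class StackSpec:
    """Two stacked rings: ring B is ring A flipped (optionally), rotated by
    Δ about z, tilted by δ about x, and raised along z."""

    ring: RingSpec = field(default_factory=RingSpec)
    delta_deg: float = 0.0
    tilt_deg: float = 0.0
    rise: float = 33.0
    flip_second_ring: bool = True
    #: Å; systematic template deformation applied to every ring-B subunit
    #: (same deformation for all six), emulating the distinct conformer
    #: populations of the two rings in a real double-ring assembly
    ring_b_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if abs(self.tilt_deg) >= 30:
            raise ValueError("|tilt| must be below 30 degrees")


@dataclass(frozen=True)
class FPSimSpec:
    """Simulated fluorescence-polarization titration."""

    model_kind: str  # 'logistic4' | 'depletion'
    true_params: dict
    conc_grid: tuple  # titrant concentrations, M, strictly positive ascending
    n_reps: int = 3
    noise_sd_mP: float = 0.0
    seed: int = 0
    probe_total: float | None = None  # M; required for the depletion model

    def __post_init__(self) -> None:
        grid = np.asarray(self.conc_grid, float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("conc_grid must be strictly positive and ascending")
        if self.n_reps < 1:
            raise ValueError("n_reps must be ≥ 1")
        if self.model_kind not in ("logistic4", "depletion"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")


# ---------------------------------------------------------------------------
# rings
# ---------------------------------------------------------------------------

def _subunit_atoms(coords: np.ndarray, chain_id: str) -> list[AtomRecord]:
    # every template point is exposed as a CA node so that the CA preset,
    # the main-chain preset and the elastic-network builder all see it
    return [
        AtomRecord(
            serial=0,
            name="CA",
            element="C",
            alt_loc="",
            res_name="GLY",
            chain_id=chain_id,
            res_seq=i + 1,
            i_code="",
            xyz=xyz,
            occupancy=1.0,
            b_iso=10.0,
        )
        for i, xyz in enumerate(coords)
    ]


def _assemble(all_coords: list[np.ndarray], chain_ids: list[str], title: str) -> StructureModel:
    atoms: list[AtomRecord] = []
    for coords, cid in zip(all_coords, chain_ids):
        atoms.extend(_subunit_atoms(coords, cid))
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return StructureModel(atoms=atoms, title=title)


def _ring_coords(spec: RingSpec) -> list[np.ndarray]:
    """Noise-free subunit coordinate blocks; subunit k sits at azimuth k·360°/n,
    subunit 0 exactly on the +x axis."""
    template = spec.template_coords()
    blocks = []
    for k in range(spec.n_subunits):
        R = rotation_about_axis((0, 0, 1), 360.0 * k / spec.n_subunits)
        blocks.append((template + np.array([spec.radius, 0.0, 0.0])) @ R.T)
    return blocks


def make_ring(spec: RingSpec) -> StructureModel:
    """n rotational copies of the template at the given radius, plus
    i.i.d. per-coordinate Gaussian noise; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    blocks = _ring_coords(spec)
    if spec.noise_sigma > 0:
        blocks = [b + rng.normal(0.0, spec.noise_sigma, b.shape) for b in blocks]
    return _assemble(blocks, list(_CHAINS[: spec.n_subunits]), f"synthetic C{spec.n_subunits} ring")


def make_stacked_rings(spec: StackSpec) -> StructureModel:
    """Head-to-tail (or parallel) double ring.

    Ring B is built from the same noise-free ring as ring A, transformed by
    (flip about x) → rotation Δ about z → tilt δ about x → translation
    ``rise`` along z, in that order; independent noise is then added to the
    two rings.  Chains continue alphabetically from ring A into ring B.
    """
    rng = np.random.default_rng(spec.ring.seed)
    base = _ring_coords(spec.ring)
    n = spec.ring.n_subunits

    base_b = base
    if spec.ring_b_perturbation > 0:
        # one fixed deformation shared by all ring-B subunits, so the two
        # rings form two internally homogeneous conformer populations
        prng = np.random.default_rng(spec.ring.seed + 104729)
        template_b = spec.ring.template_coords() + prng.normal(
            0.0, spec.ring_b_perturbation, spec.ring.template_coords().shape
        )
        spec_b = RingSpec(n_subunits=n, radius=spec.ring.radius, noise_sigma=0.0,
                          seed=spec.ring.seed, template=template_b)
        base_b = _ring_coords(spec_b)

    R = rotation_about_axis((1, 0, 0), spec.tilt_deg) @ rotation_about_axis((0, 0, 1), spec.delta_deg)
    if spec.flip_second_ring:
        R = R @ rotation_about_axis((1, 0, 0), 180.0)
    shift = np.array([0.0, 0.0, spec.rise])

    ring_a = [b.copy() for b in base]
    ring_b = [b @ R.T + shift for b in base_b]
    if spec.ring.noise_sigma > 0:
        ring_a = [b + rng.normal(0.0, spec.ring.noise_sigma, b.shape) for b in ring_a]
        ring_b = [b + rng.normal(0.0, spec.ring.noise_sigma, b.shape) for b in ring_b]
    chains = list(_CHAINS[:n]) + list(_CHAINS[n : 2 * n])
    return _assemble(ring_a + ring_b, chains, f"synthetic stacked C{n} double ring")


# ---------------------------------------------------------------------------
# furanose / nucleoside geometry
# ---------------------------------------------------------------------------

# furanose ring atoms in pseudorotation order; torsion ν_j is about the
# bond (ring[(j+1) % 5], ring[(j+2) % 5]) in the standard convention
RING_ATOMS = ("C4'", "O4'", "C1'", "C2'", "C3'")
_RING_BONDS = {  # Å, idealized ribose
    ("C4'", "O4'"): 1.453,
    ("O4'", "C1'"): 1.414,
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.524,
}
_RING_ANGLES = {  # degrees
    ("C4'", "O4'", "C1'"): 109.7,
    ("O4'", "C1'", "C2'"): 106.1,
    ("C1'", "C2'", "C3'"): 101.5,
    ("C2'", "C3'", "C4'"): 102.6,
    ("C3'", "C4'", "O4'"): 105.5,
}


def nu_targets(P_deg: float, nu_max: float) -> np.ndarray:
    """Endocyclic torsions ν0..ν4 of the pseudorotation model,
    ν_j = ν_max·cos(P + 144°·(j−2)) so that ν2 = ν_max·cos P."""
    j = np.arange(5)
    return nu_max * np.cos(np.deg2rad(P_deg + 144.0 * (j - 2)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: position of atom D given A–B–C, the C–D
    bond length, the B–C–D angle and the A–B–C–D torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(180.0 - angle_deg)
    tor = -np.deg2rad(torsion_deg)  # sign such that dihedral(a, b, c, result) == torsion_deg
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion(p1, p2, p3, p4) -> float:
    from .na_geometry import dihedral

    return dihedral(p1, p2, p3, p4)


def _build_furanose(P_deg: float, nu_max: float) -> dict[str, np.ndarray]:
    """Sequentially place the five ring atoms, then refine all five against
    the target bonds/angles/torsions (torsions weighted heavily) so the
    requested pseudorotation state is met to well under a degree."""
    nu = nu_targets(P_deg, nu_max)
    pos: dict[str, np.ndarray] = {}
    # seed chain C4'→O4'→C1' in a plane
    pos["C4'"] = np.zeros(3)
    pos["O4'"] = np.array([_RING_BONDS[("C4'", "O4'")], 0.0, 0.0])
    ang = np.deg2rad(180.0 - _RING_ANGLES[("C4'", "O4'", "C1'")])
    pos["C1'"] = pos["O4'"] + _RING_BONDS[("O4'", "C1'")] * np.array([np.cos(ang), np.sin(ang), 0.0])
    # ν0 is about O4'–C1' (C4'-O4'-C1'-C2'), ν1 about C1'–C2'
    pos["C2'"] = place_atom(pos["C4'"], pos["O4'"], pos["C1'"], _RING_BONDS[("C1'", "C2'")],
                            _RING_ANGLES[("O4'", "C1'", "C2'")], nu[0])
    pos["C3'"] = place_atom(pos["O4'"], pos["C1'"], pos["C2'"], _RING_BONDS[("C2'", "C3'")],
                            _RING_ANGLES[("C1'", "C2'", "C3'")], nu[1])

    names = list(RING_ATOMS)
    x0 = np.concatenate([pos[n] for n in names])

    bond_pairs = list(_RING_BONDS.items())
    angle_triples = list(_RING_ANGLES.items())
    torsion_quads = [tuple(names[(j + k) % 5] for k in range(4)) for j in range(5)]
    # torsion ν_j runs over atoms (ring[j], ring[j+1], ring[j+2], ring[j+3])
    # starting at C4' for ν4 ... easier: enumerate explicitly
    torsion_quads = [
        ("C4'", "O4'", "C1'", "C2'"),  # ν0
        ("O4'", "C1'", "C2'", "C3'"),  # ν1
        ("C1'", "C2'", "C3'", "C4'"),  # ν2
        ("C2'", "C3'", "C4'", "O4'"),  # ν3
        ("C3'", "C4'", "O4'", "C1'"),  # ν4
    ]

    def residuals(x: np.ndarray) -> np.ndarray:
        p = {n: x[3 * i : 3 * i + 3] for i, n in enumerate(names)}
        res = []
        for (a, b), length in bond_pairs:
            res.append(5.0 * (np.linalg.norm(p[a] - p[b]) - length))
        for (a, b, c), angle in angle_triples:
            v1 = p[a] - p[b]
            v2 = p[c] - p[b]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            res.append(0.05 * (np.rad2deg(np.arccos(np.clip(cosang, -1, 1))) - angle))
        for quad, target in zip(torsion_quads, nu):
            diff = _torsion(*(p[n] for n in quad)) - target
            res.append(0.5 * ((diff + 180.0) % 360.0 - 180.0))
        return np.array(res)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    p = {n: sol.x[3 * i : 3 * i + 3] for i, n in enumerate(names)}
    closure = abs(np.linalg.norm(p["C3'"] - p["C4'"]) - _RING_BONDS[("C3'", "C4'")])
    if closure > 0.1:
        raise RuntimeError(f"furanose ring closure residual {closure:.3f} Å exceeds 0.1 Å")
    return p


def make_sugar_ring(P_deg: float, nu_max: float = 38.0, chi_deg: float = -160.0) -> StructureModel:
    """One uridine ribonucleoside with the requested sugar pucker and
    glycosidic torsion.

    The furanose is embedded with standard bond lengths/angles so that its
    endocyclic torsions follow ν_j = ν_max·cos(P + 144°(j−2)); the uracil
    base is attached planar with χ = (O4'–C1'–N1–C2) as requested.
    """
    if not 20.0 < nu_max < 50.0:
        raise ValueError("nu_max must lie in (20°, 50°)")
    pos = _build_furanose(P_deg, nu_max)
    nu = nu_targets(P_deg, nu_max)

    # exocyclic sugar substituents (torsions: standard-ish, not load-bearing)
    pos["O3'"] = place_atom(pos["C1'"], pos["C2'"], pos["C3'"], 1.42, 110.0, nu[1] - 120.0)
    pos["O2'"] = place_atom(pos["O4'"], pos["C1'"], pos["C2'"], 1.41, 110.0, nu[0] + 120.0)
    pos["C5'"] = place_atom(pos["C2'"], pos["C3'"], pos["C4'"], 1.51, 115.0, nu[2] - 120.0)
    pos["O5'"] = place_atom(pos["C3'"], pos["C4'"], pos["C5'"], 1.42, 111.0, 180.0)

    # base: N1 on the face opposite C2', then the pyrimidine ring planar
    nu0 = _torsion(pos["C4'"], pos["O4'"], pos["C1'"], pos["C2'"])
    pos["N1"] = place_atom(pos["C4'"], pos["O4'"], pos["C1'"], 1.48, 108.2, nu0 - 122.0)
    pos["C2"] = place_atom(pos["O4'"], pos["C1'"], pos["N1"], 1.38, 117.0, chi_deg)
    pos["C6"] = place_atom(pos["O4'"], pos["C1'"], pos["N1"], 1.38, 121.0, chi_deg + 180.0)
    pos["N3"] = place_atom(pos["C6"], pos["N1"], pos["C2"], 1.37, 121.0, 0.0)
    pos["C4"] = place_atom(pos["N1"], pos["C2"], pos["N3"], 1.38, 121.0, 0.0)
    pos["C5"] = place_atom(pos["C2"], pos["N3"], pos["C4"], 1.44, 121.0, 0.0)
    pos["O2"] = place_atom(pos["C6"], pos["N1"], pos["C2"], 1.22, 119.5, 180.0)
    pos["O4"] = place_atom(pos["C2"], pos["N3"], pos["C4"], 1.23, 119.5, 180.0)

    order = ["O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
             "N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            element=name[0],
            alt_loc="",
            res_name="U",
            chain_id="R",
            res_seq=1,
            i_code="",
            xyz=pos[name],
            occupancy=1.0,
            b_iso=15.0,
        )
        for i, name in enumerate(order)
    ]
    return StructureModel(atoms=atoms, title=f"synthetic uridine P={P_deg:g} chi={chi_deg:g}")


# ---------------------------------------------------------------------------
# fluorescence-polarization titrations
# ---------------------------------------------------------------------------

def simulate_fp(spec: FPSimSpec) -> FPDataset:
    """Noisy replicate titration drawn from the chosen isotherm model."""
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.conc_grid, float)
    if spec.model_kind == "logistic4":
        params = Logistic4Params(**spec.true_params)
        clean = eval_logistic4(np.log10(grid), params)
        probe_total = spec.probe_total
    else:
        params = DepletionParams(**spec.true_params)
        clean = eval_depletion(grid, params)
        probe_total = spec.probe_total if spec.probe_total is not None else params.probe_total
    rows = []
    for rep in range(1, spec.n_reps + 1):
        noise = rng.normal(0.0, spec.noise_sd_mP, grid.size) if spec.noise_sd_mP > 0 else 0.0
        mp = clean + noise
        for conc, value in zip(grid, np.atleast_1d(mp) if np.ndim(mp) else mp):
            rows.append((conc, rep, float(value)))
    return FPDataset.from_rows(rows, probe_total=probe_total,
                               metadata={"source": "simulate_fp", "model_kind": spec.model_kind,
                                         "seed": spec.seed})
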