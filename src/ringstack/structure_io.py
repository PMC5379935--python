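"""Macromolecular coordinate container and PDB input/output.

The in-memory model is a flat, ordered list of atom records grouped
logically by chain and residue.  Coordinates are orthogonal Ångström
(PDB convention); anisotropic displacement parameters, when present,
are carried per atom on the absolute U scale (Å², i.e. ANISOU integer
values divided by 10⁴).  Reading and writing go through gemmi so that
all fixed-width PDB conventions (ATOM/HETATM/ANISOU/CRYST1/MODEL/TER)
are handled by a battle-tested parser; this module only maps between
gemmi's hierarchy and the lightweight records used by the analyses.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import gemmi

__all__ = [
    "AtomRecord",
    "UnitCell",
    "StructureModel",
    "Selection",
    "EmptySelectionWarning",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "expand_rotational_symmetry",
    "select_atoms",
]

# atom-name sets for the named selection presets
MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

#: labels available for chain re-naming during symmetry expansion
_CHAIN_LABELS = string.ascii_uppercase + string.ascii_lowercase + string.digits


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptySelectionWarning(UserWarning):
    """Emitted when a selection matches no atoms (never silently empty)."""


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180) degrees")


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    u_aniso: tuple[float, float, float, float, float, float] | None = None
    is_het: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: xyz must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} {self.name}: occupancy outside [0, 1]")
        if self.u_aniso is not None:
            u11, u22, u33 = self.u_aniso[:3]
            if min(u11, u22, u33) <= 0:
                raise ValueError(f"atom {self.serial} {self.name}: diagonal U must be positive")

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code, self.name, self.alt_loc)

    def copy(self) -> "AtomRecord":
        rec = replace(self)
        rec.xyz = self.xyz.copy()
        return rec


@dataclass
class StructureModel:
    """Ordered atom container with optional unit cell.

    Atom identity (chain, residue number, insertion code, atom name,
    altloc) is unique; residue order within a chain is monotone in the
    residue number, matching deposited-file conventions.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    cell: UnitCell | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple] = set()
        last_seq: dict[str, tuple[int, str]] = {}
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom identity {a.key}")
            seen.add(a.key)
            prev = last_seq.get(a.chain_id)
            if prev is not None and (a.res_seq, a.i_code) < prev:
                raise ValueError(
                    f"residue order not monotone in chain {a.chain_id!r} at {a.res_seq}{a.i_code}"
                )
            last_seq[a.chain_id] = (a.res_seq, a.i_code)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.xyz for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.xyz = p.copy()

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> list[tuple[str, int, str, str, list[AtomRecord]]]:
        """Group atoms into (chain_id, res_seq, i_code, res_name, atoms) in file order."""
        groups: list[tuple[str, int, str, str, list[AtomRecord]]] = []
        key = None
        for a in self.atoms:
            k = (a.chain_id, a.res_seq, a.i_code)
            if k != key:
                groups.append((a.chain_id, a.res_seq, a.i_code, a.res_name, []))
                key = k
            groups[-1][4].append(a)
        return groups

    def copy(self) -> "StructureModel":
        return StructureModel(atoms=[a.copy() for a in self.atoms], cell=self.cell, title=self.title)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy: x ↦ R·x + t."""
        out = self.copy()
        out.set_coords(self.coords() @ np.asarray(rotation, float).T + np.asarray(translation, float))
        return out

    def het_inventory(self) -> dict[str, int]:
        """Residue counts of heteroatom groups, e.g. {'MPD': 25, 'HOH': 310}."""
        counts: dict[str, int] = {}
        for _, _, _, res_name, atoms in self.residues():
            if atoms[0].is_het:
                counts[res_name] = counts.get(res_name, 0) + 1
        return counts


@dataclass(frozen=True)
class Selection:
    """Declarative atom-subset query.

    Any combination of constraints may be given; ``preset`` expands to an
    atom-name set ('main-chain' → N, CA, C, O; 'CA' → CA).  ``het`` set to
    True/False restricts to heteroatoms/polymer atoms.
    """

    chains: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None
    names: frozenset[str] | None = None
    het: bool | None = None
    preset: str | None = None

    PRESETS = {"main-chain": frozenset(MAIN_CHAIN_ATOMS), "CA": frozenset({"CA"})}

    def atom_names(self) -> frozenset[str] | None:
        if self.preset is not None:
            if self.preset not in self.PRESETS:
                raise ValueError(f"unknown selection preset {self.preset!r}")
            base = self.PRESETS[self.preset]
            return base if self.names is None else base | self.names
        return self.names

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.res_range is not None:
            lo, hi = self.res_range
            if not lo <= atom.res_seq <= hi:
                return False
        names = self.atom_names()
        if names is not None and atom.name not in names:
            return False
        if self.het is not None and atom.is_het != self.het:
            return False
        return True

    @staticmethod
    def parse_chains(expr: str) -> tuple[str, ...]:
        """Parse 'A-F' / 'A,C,E' / 'AF' style chain lists into a tuple."""
        out: list[str] = []
        for tok in expr.split(","):
            tok = tok.strip()
            if len(tok) == 3 and tok[1] == "-":
                lo, hi = ord(tok[0]), ord(tok[2])
                if hi < lo:
                    raise ValueError(f"bad chain range {tok!r}")
                out.extend(chr(c) for c in range(lo, hi + 1))
            elif tok:
                out.extend(tok)
        return tuple(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, model_index: int, keep_alt_locs: bool) -> StructureModel:
    if model_index < 1 or model_index > len(st):
        raise FileNotFoundError(
            f"model {model_index} not present ({len(st)} model(s) in file)"
        )
    model = st[model_index - 1]
    cell = None
    c = st.cell
    if c.a > 1.0:  # gemmi uses a dummy 1 Å cell when CRYST1 is absent
        cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma, st.spacegroup_hm or "P 1")
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if keep_alt_locs or atom.altloc == "\0" or atom.altloc == "":
                    best[atom.name + atom.altloc] = atom
                else:
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        best[atom.name] = atom
            for atom in best.values():
                an = atom.aniso
                u = None
                if an.nonzero():
                    u = (an.u11, an.u22, an.u33, an.u12, an.u13, an.u23)
                alt = atom.altloc if atom.altloc not in ("\0", "") else ""
                if not keep_alt_locs:
                    alt = ""  # collapsing to one conformer removes the altloc distinction
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        alt_loc=alt,
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        i_code=res.seqid.icode.strip(),
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_iso=atom.b_iso,
                        u_aniso=u,
                        is_het=(res.het_flag == "H"),
                    )
                )
    return StructureModel(atoms=atoms, cell=cell, title=st.name or "")


def _validate_fixed_width(path) -> None:
    """Reject coordinate lines whose numeric fields do not parse (the
    underlying reader would silently zero them otherwise)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: coordinate record too short")
            for lo, hi, field in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable {field} coordinate {line[lo:hi]!r}"
                    ) from None


def read_structure(path, model_index: int = 1, keep_alt_locs: bool = False) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    By default the highest-occupancy alternate conformer of each atom is
    kept and model 1 of a multi-model file is used.
    """
    _validate_fixed_width(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no coordinate models found")
    return _from_gemmi(st, model_index, keep_alt_locs)


def write_structure(model: StructureModel, path) -> None:
    """Write a model as PDB (coordinates to 3 decimals, occ/B to 2, U·10⁴ on ANISOU)."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.title
    if model.cell is not None:
        c = model.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        st.spacegroup_hm = c.space_group
    gm = gemmi.Model("1")
    serial = 0
    for chain_id in model.chain_ids():
        if len(chain_id) != 1:
            raise ValueError(f"chain id {chain_id!r} not encodable in PDB format")
        chain = gemmi.Chain(chain_id)
        for cid, res_seq, i_code, res_name, recs in model.residues():
            if cid != chain_id:
                continue
            if len(res_name) > 3 or res_seq < -999 or res_seq > 9999:
                raise ValueError(f"residue {res_name} {res_seq} not encodable in PDB format")
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_seq, i_code if i_code else " ")
            res.het_flag = "H" if recs[0].is_het else "A"
            for rec in recs:
                a = gemmi.Atom()
                a.name = rec.name
                a.element = gemmi.Element(rec.element)
                a.altloc = rec.alt_loc if rec.alt_loc else "\0"
                a.pos = gemmi.Position(*rec.xyz)
                a.occ = rec.occupancy
                a.b_iso = rec.b_iso
                serial += 1
                a.serial = serial
                if rec.u_aniso is not None:
                    u = rec.u_aniso
                    a.aniso = gemmi.SMat33f(u[0], u[1], u[2], u[3], u[4], u[5])
                res.add_atom(a)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# transforms & selection
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a rotation of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be nonzero")
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm).as_matrix()


def expand_rotational_symmetry(
    model: StructureModel,
    fold: int,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> StructureModel:
    """Generate ``fold`` rotational copies about ``axis`` through ``origin``.

    Copy k is the input rotated by k·360°/fold; chains are relabeled
    uniquely (A, B, … continuing past the input labels).
    """
    if fold < 1:
        raise ValueError("fold must be ≥ 1")
    origin = np.asarray(origin, float)
    used = set(model.chain_ids())
    available = [c for c in _CHAIN_LABELS if c not in used]
    n_new_chains = len(model.chain_ids()) * (fold - 1)
    if n_new_chains > len(available):
        raise ValueError("chain labels exhausted during symmetry expansion")
    out = model.copy()
    label_iter = iter(available)
    for k in range(1, fold):
        R = rotation_about_axis(axis, 360.0 * k / fold)
        relabel = {c: next(label_iter) for c in model.chain_ids()}
        for a in model.atoms:
            b = a.copy()
            b.xyz = R @ (a.xyz - origin) + origin
            b.chain_id = relabel[a.chain_id]
            out.atoms.append(b)
    out.validate()
    return out


def select_atoms(model: StructureModel, query: Selection) -> StructureModel:
    """Subset of ``model`` matching ``query``, order and identifiers preserved."""
    atoms = [a.copy() for a in model.atoms if query.matches(a)]
    if not atoms:
        warnings.warn(f"selection {query} matched no atoms", EmptySelectionWarning, stacklevel=2)
    return StructureModel(atoms=atoms, cell=model.cell, title=model.title)
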