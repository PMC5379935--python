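"""Anisotropic network model (ANM) normal modes and ADP utilities.

The assembly is coarse-grained to its CA atoms; pairs within a cutoff
(default 15 Å) are joined by harmonic springs of uniform force constant
γ (default 1, arbitrary units).  The 3N×3N Hessian has the standard
super-element form, its eigen-decomposition gives the vibrational
spectrum: a connected contact network has exactly six zero modes
(rigid-body translations/rotations), and the softest nontrivial modes
describe the large-scale collective motions.  ``ring_rotation_overlap``
quantifies how much a mode looks like an antisymmetric counter-rotation
of two rings about a common axis.

B_eq = 8π²·tr(U)/3 converts an anisotropic displacement tensor to the
equivalent isotropic B value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import Selection, StructureModel, select_atoms

__all__ = [
    "ANMModel",
    "AnisoADP",
    "build_anm",
    "mode_shapes",
    "ring_rotation_overlap",
    "b_eq",
    "beq_from_model",
]

ZERO_MODE_REL_TOL = 1e-6  # λ < tol·λ_max counts as a rigid-body mode


@dataclass
class ANMModel:
    nodes: np.ndarray  # (N, 3) CA coordinates, Å
    gamma: float
    cutoff: float
    hessian: np.ndarray  # 3N×3N
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    n_components: int  # connected components of the contact graph
    node_chain_ids: list

    @property
    def n_zero_modes(self) -> int:
        lam_max = self.eigenvalues[-1]
        return int(np.sum(self.eigenvalues < ZERO_MODE_REL_TOL * lam_max))

    def nontrivial(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) with the zero modes stripped."""
        k = self.n_zero_modes
        return self.eigenvalues[k:], self.eigenvectors[:, k:]


@dataclass
class AnisoADP:
    u: tuple  # (U11, U22, U33, U12, U13, U23), Å²
    b_eq: float  # Å²
    principal_u: tuple
    non_positive_flag: bool = False


def build_anm(model: StructureModel, gamma: float = 1.0, cutoff: float = 15.0) -> ANMModel:
    """Elastic-network Hessian and full spectrum for the CA nodes of ``model``.

    Off-diagonal super-element for a contacting pair (i, j):
    −γ·(r_ij r_ijᵀ)/|r_ij|²; diagonal blocks are minus the sum of the
    off-diagonal blocks in their row.  A disconnected contact graph
    triggers a warning (zero modes then exceed six).
    """
    if gamma <= 0 or cutoff <= 0:
        raise ValueError("gamma and cutoff must be positive")
    ca = select_atoms(model, Selection(preset="CA", het=False))
    if len(ca) < 2:
        raise ValueError("need at least 2 CA nodes")
    nodes = ca.coords()
    n = len(nodes)
    pairs = cKDTree(nodes).query_pairs(cutoff, output_type="ndarray")
    hessian = np.zeros((3 * n, 3 * n))
    adjacency = np.zeros((n, n), dtype=bool)
    for i, j in pairs:
        rij = nodes[j] - nodes[i]
        d2 = float(rij @ rij)
        if d2 == 0.0:
            continue
        block = -gamma * np.outer(rij, rij) / d2
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
        adjacency[i, j] = adjacency[j, i] = True
    n_comp = int(connected_components(adjacency, directed=False)[0])
    if n_comp > 1:
        warnings.warn(f"contact graph has {n_comp} components; zero modes exceed 6",
                      UserWarning, stacklevel=2)
    eigenvalues, eigenvectors = eigh(hessian)
    return ANMModel(nodes=nodes, gamma=gamma, cutoff=cutoff, hessian=hessian,
                    eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                    n_components=n_comp, node_chain_ids=[a.chain_id for a in ca])


def mode_shapes(anm: ANMModel, k: int) -> list[np.ndarray]:
    """Per-node displacement fields of the k softest nontrivial modes,
    each a unit-norm (N, 3) array, ordered by ascending eigenvalue."""
    lam, vec = anm.nontrivial()
    if not 1 <= k <= len(lam):
        raise ValueError(f"k must be in [1, {len(lam)}]")
    n = len(anm.nodes)
    return [vec[:, m].reshape(n, 3) for m in range(k)]


def _rotation_field(nodes: np.ndarray, axis: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.cross(np.broadcast_to(axis, nodes.shape), nodes - center)


def ring_rotation_overlap(anm: ANMModel, ring_a_nodes: np.ndarray, ring_b_nodes: np.ndarray,
                          axis, k: int | None = None) -> list[dict]:
    """Cosine overlap of each nontrivial mode with the antisymmetric
    counter-rotation field (+ω×r on ring A nodes, −ω×r on ring B) about
    ``axis`` through the overall node centroid.

    ``ring_a_nodes``/``ring_b_nodes`` are index arrays partitioning the
    nodes.  Returns one row per mode: index, eigenvalue, overlap.
    """
    axis = np.asarray(axis, float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis must be nonzero")
    axis = axis / np.linalg.norm(axis)
    ia = np.asarray(ring_a_nodes, int)
    ib = np.asarray(ring_b_nodes, int)
    n = len(anm.nodes)
    if sorted(np.concatenate([ia, ib]).tolist()) != list(range(n)):
        raise ValueError("ring node sets must partition the nodes")
    center = anm.nodes.mean(axis=0)
    field = np.zeros((n, 3))
    field[ia] = _rotation_field(anm.nodes[ia], axis, center)
    field[ib] = -_rotation_field(anm.nodes[ib], axis, center)
    field = field.ravel()
    field /= np.linalg.norm(field)
    lam, vec = anm.nontrivial()
    k = len(lam) if k is None else min(k, len(lam))
    rows = []
    for m in range(k):
        rows.append({
            "mode": m + 1,
            "eigenvalue": float(lam[m]),
            "overlap": abs(float(vec[:, m] @ field)),
        })
    return rows


def b_eq(u) -> float:
    """Equivalent isotropic B from an anisotropic U tensor:
    B_eq = 8π²·(U11 + U22 + U33)/3 (Å²)."""
    u = tuple(float(v) for v in u)
    if len(u) != 6 or not all(np.isfinite(u)):
        raise ValueError("u must be a finite 6-tuple (U11,U22,U33,U12,U13,U23)")
    return 8.0 * np.pi**2 * (u[0] + u[1] + u[2]) / 3.0


def aniso_adp(u) -> AnisoADP:
    """Full ADP report: B_eq plus principal U values (eigenvalues of the
    symmetric U matrix); a non-positive trace is flagged, not fatal."""
    u = tuple(float(v) for v in u)
    U = np.array([[u[0], u[3], u[4]], [u[3], u[1], u[5]], [u[4], u[5], u[2]]])
    principal = tuple(float(x) for x in np.linalg.eigvalsh(U))
    trace = u[0] + u[1] + u[2]
    return AnisoADP(u=u, b_eq=8.0 * np.pi**2 * trace / 3.0,
                    principal_u=principal, non_positive_flag=trace <= 0)


def beq_from_model(model: StructureModel) -> list[dict]:
    """Per-atom B_eq for atoms carrying anisotropic ADPs; atoms without a
    tensor report their refined isotropic B."""
    rows = []
    for a in model.atoms:
        if a.u_aniso is not None:
            rows.append({"atom": a.key, "b_eq": b_eq(a.u_aniso), "source": "aniso"})
        else:
            rows.append({"atom": a.key, "b_eq": a.b_iso, "source": "iso"})
    return rows
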