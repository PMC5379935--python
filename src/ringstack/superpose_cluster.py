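"""Pairwise/multiple superposition, RMSD matrices, clustering, rotamers.

Superposition is least-squares rigid-body fitting (Kabsch, via SVD)
with the determinant sign corrected so that only proper rotations are
returned.  RMSD distance matrices over ring subunits feed agglomerative
hierarchical clustering (complete linkage, or Ward treating the RMSD
matrix as a Euclidean dissimilarity — a convention, not a metric
guarantee).  A mean-reference alignment iterates align-all/average
until the mean converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .structure_io import Selection, StructureModel, select_atoms
from .na_geometry import dihedral

__all__ = [
    "SuperpositionResult",
    "DistanceMatrix",
    "ClusterTree",
    "superpose_pair",
    "superpose_coords",
    "rmsd_matrix",
    "mean_reference",
    "hierarchical_cluster",
    "cut_tree",
    "similarity_edges",
    "sidechain_chi_compare",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3×3 proper rotation
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be orthonormal with determinant +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def mean_offdiag(self) -> float:
        n = len(self.labels)
        return float(self.condensed().mean()) if n > 1 else 0.0


@dataclass
class ClusterTree:
    """Agglomerative merge sequence in scipy linkage form."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) Z matrix
    linkage: str  # 'complete' | 'ward'
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        newick = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.linkage_matrix):
            i, j = int(i), int(j)
            node = n + k
            bi = h - height[i]
            bj = h - height[j]
            newick[node] = f"({newick[i]}:{bi:.6g},{newick[j]}:{bj:.6g})"
            height[node] = h
        return newick[n + len(self.linkage_matrix) - 1] + ";"


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (N×3 each).

    Returns the proper rotation R and translation t minimizing
    ‖R·x + t − y‖; mirror solutions are excluded by flipping the sign of
    the smallest singular direction when det < 0.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching N×3")
    if len(P) < 3:
        raise ValueError("need at least 3 matched atoms")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def _matched_coords(mobile: StructureModel, reference: StructureModel,
                    selection: Selection | None) -> tuple[np.ndarray, np.ndarray]:
    sel = selection or Selection()
    ma = [a for a in mobile.atoms if sel.matches(a)]
    ra = [a for a in reference.atoms if sel.matches(a)]
    ref_index = {(a.res_seq, a.i_code, a.name): a for a in ra}
    mob_index = {(a.res_seq, a.i_code, a.name): a for a in ma}
    common = [k for k in ((a.res_seq, a.i_code, a.name) for a in ra) if k in mob_index]
    if len(common) != len(ra) or len(common) != len(ma):
        mismatch = next((k for k in ref_index if k not in mob_index), None) or next(
            (k for k in mob_index if k not in ref_index), None)
        raise ValueError(f"atom sets differ; first unmatched atom: {mismatch}")
    if len(common) < 3:
        raise ValueError(f"fewer than 3 matched atoms ({len(common)})")
    P = np.vstack([mob_index[k].xyz for k in common])
    Q = np.vstack([ref_index[k].xyz for k in common])
    return P, Q


def superpose_pair(mobile: StructureModel, reference: StructureModel,
                   selection: Selection | None = None) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` over atoms matched by
    (residue number, insertion code, atom name) within the selection."""
    P, Q = _matched_coords(mobile, reference, selection)
    return superpose_coords(P, Q)


def rmsd_matrix(models: list[StructureModel], selection: Selection | None = None,
                labels: list[str] | None = None) -> DistanceMatrix:
    """All-pairs superposition RMSD matrix."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    labels = labels or [m.title or f"model{i}" for i, m in enumerate(models)]
    n = len(models)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = superpose_pair(models[i], models[j], selection)
            except ValueError as exc:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
            d[i, j] = d[j, i] = r.rmsd
    return DistanceMatrix(labels=list(labels), d=d)


@dataclass
class MeanReference:
    model: StructureModel
    n_iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def mean_reference(models: list[StructureModel], selection: Selection | None = None,
                   max_iter: int = 20, tol: float = 1e-4) -> MeanReference:
    """Iterative mean structure: align every model to the running mean,
    average coordinates, repeat until the mean moves less than ``tol`` Å.

    The first model's identifiers are kept for the returned mean.
    """
    if not models:
        raise ValueError("no models given")
    if max_iter < 1:
        raise ValueError("max_iter must be ≥ 1")
    sel = selection or Selection()
    subsets = [select_atoms(m, sel) for m in models]
    if len(models) == 1:
        return MeanReference(model=subsets[0], n_iterations=1, converged=True)
    coord_sets = []
    ref = subsets[0]
    for s in subsets:
        P, Q = _matched_coords(s, ref, None)
        coord_sets.append(P)
    if any(c.shape != coord_sets[0].shape for c in coord_sets):
        raise ValueError("models do not share a common matched atom set")

    mean = coord_sets[0].copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [superpose_coords(c, mean).apply(c) for c in coord_sets]
        new_mean = np.mean(aligned, axis=0)
        trace.append(float(sum(np.mean(np.sum((a - new_mean) ** 2, axis=1)) for a in aligned)))
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    out = ref.copy()
    out.set_coords(mean)
    out.title = "mean reference"
    return MeanReference(model=out, n_iterations=it, converged=converged, objective_trace=trace)


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "ward") -> ClusterTree:
    """Agglomerative clustering of a distance matrix.

    ``complete`` uses the matrix directly; ``ward`` consumes it as if it
    were a Euclidean dissimilarity.  Leaves are pre-sorted by label so
    that equal-distance merges break ties lexicographically.
    """
    if linkage not in ("complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if np.any(~np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite values")
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 leaves")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)]
    Z = sch.linkage(squareform(d, checks=False), method=linkage)
    return ClusterTree(linkage_matrix=Z, linkage=linkage, labels=labels)


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Partition into k groups by undoing the top k−1 merges."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    assignment = sch.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    return {lab: int(g) for lab, g in zip(tree.labels, assignment)}


def similarity_edges(dm: DistanceMatrix, levels: int, max_weight: float = 1e6) -> list[tuple[str, str, float]]:
    """Weighted similarity edges for the deepest dendrogram levels.

    The ``levels`` smallest off-diagonal distances (the deepest merges)
    become edges with weight 1/rmsd; zero distances are capped at
    ``max_weight``.
    """
    n = len(dm.labels)
    pairs = [(dm.d[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda t: (t[0], dm.labels[t[1]], dm.labels[t[2]]))
    edges = []
    for dist, i, j in pairs[: max(0, levels)]:
        w = max_weight if dist == 0 else min(1.0 / dist, max_weight)
        edges.append((dm.labels[i], dm.labels[j], float(w)))
    return edges


# side-chain χ torsion atom quadruples (IUPAC)
CHI1_ATOMS = {
    "ARG": ("N", "CA", "CB", "CG"), "ASN": ("N", "CA", "CB", "CG"),
    "ASP": ("N", "CA", "CB", "CG"), "CYS": ("N", "CA", "CB", "SG"),
    "GLN": ("N", "CA", "CB", "CG"), "GLU": ("N", "CA", "CB", "CG"),
    "HIS": ("N", "CA", "CB", "CG"), "ILE": ("N", "CA", "CB", "CG1"),
    "LEU": ("N", "CA", "CB", "CG"), "LYS": ("N", "CA", "CB", "CG"),
    "MET": ("N", "CA", "CB", "CG"), "PHE": ("N", "CA", "CB", "CG"),
    "PRO": ("N", "CA", "CB", "CG"), "SER": ("N", "CA", "CB", "OG"),
    "THR": ("N", "CA", "CB", "OG1"), "TRP": ("N", "CA", "CB", "CG"),
    "TYR": ("N", "CA", "CB", "CG"), "VAL": ("N", "CA", "CB", "CG1"),
}
CHI2_ATOMS = {
    "ARG": ("CA", "CB", "CG", "CD"), "ASN": ("CA", "CB", "CG", "OD1"),
    "ASP": ("CA", "CB", "CG", "OD1"), "GLN": ("CA", "CB", "CG", "CD"),
    "GLU": ("CA", "CB", "CG", "CD"), "HIS": ("CA", "CB", "CG", "ND1"),
    "ILE": ("CA", "CB", "CG1", "CD1"), "LEU": ("CA", "CB", "CG", "CD1"),
    "LYS": ("CA", "CB", "CG", "CD"), "MET": ("CA", "CB", "CG", "SD"),
    "PHE": ("CA", "CB", "CG", "CD1"), "PRO": ("CA", "CB", "CG", "CD"),
    "TRP": ("CA", "CB", "CG", "CD1"), "TYR": ("CA", "CB", "CG", "CD1"),
}


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed circular difference a − b folded into (−180°, 180°]."""
    return -((b_deg - a_deg + 180.0) % 360.0 - 180.0)


def _residue_chi(model: StructureModel, chain_id: str, res_seq: int) -> dict:
    atoms = {a.name: a.xyz for a in model.atoms if a.chain_id == chain_id and a.res_seq == res_seq}
    names = {a.res_name for a in model.atoms if a.chain_id == chain_id and a.res_seq == res_seq}
    if not names:
        return {"present": False}
    res_name = names.pop()
    out = {"present": True, "res_name": res_name, "chi1": None, "chi2": None, "incomplete": False}
    for key, table in (("chi1", CHI1_ATOMS), ("chi2", CHI2_ATOMS)):
        quad = table.get(res_name)
        if quad is None:
            continue
        if all(n in atoms for n in quad):
            out[key] = dihedral(*(atoms[n] for n in quad))
        else:
            out["incomplete"] = True
    return out


def sidechain_chi_compare(model_a: StructureModel, model_b: StructureModel,
                          residues: list[tuple[str, int]]) -> list[dict]:
    """Per-residue χ1/χ2 circular differences between two models.

    ``residues`` is a list of (chain_id, res_seq) pairs looked up in both
    models; residues with missing side-chain atoms are flagged rather than
    fatal.
    """
    rows = []
    for chain_id, res_seq in residues:
        ra = _residue_chi(model_a, chain_id, res_seq)
        rb = _residue_chi(model_b, chain_id, res_seq)
        row = {"chain_id": chain_id, "res_seq": res_seq,
               "res_name": ra.get("res_name") or rb.get("res_name"),
               "flagged": not (ra.get("present") and rb.get("present"))
               or ra.get("incomplete") or rb.get("incomplete"),
               "d_chi1": None, "d_chi2": None}
        for key in ("chi1", "chi2"):
            va, vb = ra.get(key), rb.get(key)
            if va is not None and vb is not None:
                row["d_" + key] = circular_difference(va, vb)
        rows.append(row)
    return rows
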