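"""Ring and double-ring geometry.

Quantifies the arrangement of cyclic oligomer rings: principal axes of
the inertia tensor (unit masses unless weights are given), best-fit
planes by singular-value decomposition, and the relative geometry of
two stacked rings — in-plane rotation Δ, tilt δ and rise.

Δ has no unique coordinate-free definition for a C_n ring, so the
operational convention used here is documented: each ring's subunit
anchors (per-chain CA centroids by default) are reduced to a C_n
order-parameter phase ψ = arg(Σ_k exp(i·n·φ_k))/n of their azimuths φ_k
about the shared ring normal, and Δ = ψ_B − ψ_A folded into
(−180°/n, 180°/n].  This is matching-free, insensitive to subunit
labelling, and exact on generated stacks (including head-to-tail
flipped rings whose first subunit sits at azimuth zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, StructureModel

__all__ = [
    "AxesResult",
    "PlaneFit",
    "StackGeometry",
    "principal_axes",
    "best_fit_plane",
    "stack_geometry",
    "subunit_anchors",
]


@dataclass
class AxesResult:
    centroid: np.ndarray
    axes: np.ndarray  # rows are unit eigenvectors, moments ascending
    moments: np.ndarray  # Å²·mass
    degenerate: bool = False


@dataclass
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray  # unit vector, +z hemisphere
    rms_residual: float


@dataclass
class StackGeometry:
    delta_deg: float
    tilt_deg: float
    rise: float
    n_fold: int
    plane_a: PlaneFit
    plane_b: PlaneFit
    axes_a: AxesResult
    axes_b: AxesResult


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude component made positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def principal_axes(coords: np.ndarray, masses: np.ndarray | None = None) -> AxesResult:
    """Eigen-decomposition of the inertia tensor about the centroid.

    Moments are sorted ascending; each axis's largest component is made
    positive for reproducibility.  Near-degenerate moment pairs (within
    10⁻⁶ relative) are flagged.
    """
    x = np.asarray(coords, float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) < 3:
        raise ValueError("need at least 3 points of shape (N, 3)")
    m = np.ones(len(x)) if masses is None else np.asarray(masses, float)
    if m.shape != (len(x),) or np.any(m <= 0):
        raise ValueError("masses must be positive, one per point")
    centroid = np.average(x, axis=0, weights=m)
    r = x - centroid
    if np.linalg.matrix_rank(r, tol=1e-8) < 2:
        raise ValueError("degenerate input: points are collinear")
    r2 = np.sum(m[:, None] * r * r)
    inertia = r2 * np.eye(3) - (m[:, None] * r).T @ r
    moments, vecs = np.linalg.eigh(inertia)
    axes = np.array([_sign_fix(vecs[:, i]) for i in range(3)])
    gaps = np.abs(np.diff(moments))
    scale = max(abs(moments[-1]), 1e-300)
    return AxesResult(centroid=centroid, axes=axes, moments=moments,
                      degenerate=bool(np.any(gaps < 1e-6 * scale)))


def best_fit_plane(coords: np.ndarray) -> PlaneFit:
    """Least-squares plane through the centroid (SVD).

    The normal is the direction of least variance, sign-fixed toward the
    +z hemisphere (ties broken toward +y, then +x).
    """
    x = np.asarray(coords, float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) < 3:
        raise ValueError("need at least 3 points of shape (N, 3)")
    centroid = x.mean(axis=0)
    r = x - centroid
    if np.linalg.matrix_rank(r, tol=1e-8) < 2:
        raise ValueError("degenerate input: points are collinear")
    _, _, vt = np.linalg.svd(r, full_matrices=False)
    normal = vt[-1]
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    rms = float(np.sqrt(np.mean((r @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, rms_residual=rms)


def subunit_anchors(ring: StructureModel, anchor_selection: Selection | None = None) -> np.ndarray:
    """Per-chain anchor points: centroid of the anchor selection (CA
    atoms by default) of each chain, in chain order."""
    sel = anchor_selection or Selection(preset="CA")
    anchors = []
    for chain_id in ring.chain_ids():
        pts = np.array([a.xyz for a in ring.atoms if a.chain_id == chain_id and sel.matches(a)])
        if len(pts) == 0:
            raise ValueError(f"chain {chain_id!r} has no anchor atoms for {sel}")
        anchors.append(pts.mean(axis=0))
    return np.vstack(anchors)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)  # 180° flip fallback
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _order_parameter_phase(points: np.ndarray, centroid: np.ndarray, normal: np.ndarray,
                           e1: np.ndarray, n_fold: int) -> float:
    """Phase (degrees, in [0, 360/n)) of the C_n order parameter of point
    azimuths about ``normal`` with in-plane reference axis ``e1``."""
    e2 = np.cross(normal, e1)
    r = points - centroid
    phi = np.arctan2(r @ e2, r @ e1)
    z = np.exp(1j * n_fold * phi).sum()
    if abs(z) < 1e-9:
        raise ValueError("degenerate azimuth distribution: no C_n phase")
    return float(np.rad2deg(np.angle(z)) / n_fold) % (360.0 / n_fold)


def fold_angle(angle_deg: float, period_deg: float) -> float:
    """Fold an angle into (−period/2, period/2]."""
    a = angle_deg % period_deg
    if a > period_deg / 2:
        a -= period_deg
    return a


def stack_geometry(ring_a: StructureModel, ring_b: StructureModel, n_fold: int,
                   anchor_selection: Selection | None = None) -> StackGeometry:
    """Relative geometry of two stacked C_n rings.

    tilt δ: angle between the ring-plane normals, folded to ≤ 90°;
    Δ: difference of the C_n order-parameter phases of subunit-anchor
    azimuths, measured about ring A's normal after rotating ring B's
    normal onto it by the minimal rotation, folded to (−180°/n, 180°/n];
    rise: centroid separation projected on ring A's normal.
    """
    anchors_a = subunit_anchors(ring_a, anchor_selection)
    anchors_b = subunit_anchors(ring_b, anchor_selection)
    if len(anchors_a) != n_fold or len(anchors_b) != n_fold:
        raise ValueError(
            f"expected {n_fold} subunit chains per ring, got {len(anchors_a)} and {len(anchors_b)}"
        )
    plane_a = best_fit_plane(anchors_a)
    plane_b = best_fit_plane(anchors_b)
    axes_a = principal_axes(anchors_a)
    axes_b = principal_axes(anchors_b)

    n_a = plane_a.normal
    n_b = plane_b.normal if np.dot(plane_b.normal, n_a) >= 0 else -plane_b.normal
    cosang = np.clip(abs(float(np.dot(plane_a.normal, plane_b.normal))), 0.0, 1.0)
    tilt = float(np.rad2deg(np.arccos(cosang)))

    # common in-plane reference axis, ⊥ n_a
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n_a)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, n_a) * n_a
    e1 /= np.linalg.norm(e1)

    R = _rotation_between(n_b, n_a)
    b_in_a = (anchors_b - plane_b.centroid) @ R.T + plane_b.centroid

    psi_a = _order_parameter_phase(anchors_a, plane_a.centroid, n_a, e1, n_fold)
    psi_b = _order_parameter_phase(b_in_a, plane_b.centroid, n_a, e1, n_fold)
    delta = fold_angle(psi_b - psi_a, 360.0 / n_fold)

    rise = abs(float(np.dot(plane_b.centroid - plane_a.centroid, n_a)))
    return StackGeometry(delta_deg=delta, tilt_deg=tilt, rise=rise, n_fold=n_fold,
                         plane_a=plane_a, plane_b=plane_b, axes_a=axes_a, axes_b=axes_b)
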