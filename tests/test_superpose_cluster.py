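import itertools

import numpy as np
import pytest

import ringstack as rs
from ringstack.structure_io import Selection, StructureModel, select_atoms
from ringstack.superpose_cluster import (
    DistanceMatrix,
    circular_difference,
    cut_tree,
    hierarchical_cluster,
    mean_reference,
    rmsd_matrix,
    similarity_edges,
    sidechain_chi_compare,
    superpose_coords,
    superpose_pair,
)

from conftest import cloud_model, point_atom


def horn_quaternion_rmsd(P, Q):
    """Independent closed-form oracle: optimal-superposition RMSD via the
    Horn quaternion eigenvalue method (no SVD)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P * P) + np.sum(Q * Q) - 2.0 * lam_max) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_complete_linkage(d):
    """Exhaustive agglomeration oracle for complete linkage: at each step
    merge the pair of clusters with the smallest maximum inter-point
    distance; returns the sorted merge heights."""
    clusters = [frozenset([i]) for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            h = max(d[i][j] for i in a for j in b)
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


class TestSuperposePair:
    def test_identical_models_zero_rmsd_identity_rotation(self):
        m = cloud_model(np.random.default_rng(0).normal(size=(8, 3)))
        r = superpose_pair(m, m)
        assert r.rmsd < 1e-12
        np.testing.assert_allclose(r.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(10, 3))
        m = cloud_model(coords)
        R = rs.structure_io.rotation_about_axis((0, 0, 1), 30.0)
        moved = cloud_model(coords @ R.T + np.array([1.0, 2.0, 3.0]))
        r = superpose_pair(moved, m)
        assert r.rmsd < 1e-9
        angle = np.rad2deg(np.arccos((np.trace(r.rotation) - 1.0) / 2.0))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_mirror_image_keeps_proper_rotation(self):
        # chiral 4-point set: no proper rotation can superpose it onto its
        # mirror (verified exhaustively against the quaternion closed form,
        # which optimizes over all proper rotations)
        P = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0.3, 0.4, 1.9]], float)
        Q = P * np.array([1, 1, -1])
        r = superpose_coords(P, Q)
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-10)
        assert r.rmsd > 0.1
        assert r.rmsd == pytest.approx(horn_quaternion_rmsd(P, Q), abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_rmsd_matches_quaternion_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(10, 3)) * 3.0
        Q = rng.normal(size=(10, 3)) * 3.0
        assert superpose_coords(P, Q).rmsd == pytest.approx(horn_quaternion_rmsd(P, Q), abs=1e-8)

    def test_too_few_atoms_raises(self):
        with pytest.raises(ValueError, match="3"):
            superpose_coords(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_mismatched_atom_sets_raise_with_first_mismatch(self):
        a = StructureModel(atoms=[point_atom(i, (i, 0, 0), name=n, res_seq=1)
                                  for i, n in enumerate(["N", "CA", "C", "O"], 1)])
        b = StructureModel(atoms=[point_atom(i, (i, 0, 0), name=n, res_seq=1)
                                  for i, n in enumerate(["N", "CA", "C", "CB"], 1)])
        with pytest.raises(ValueError, match="unmatched"):
            superpose_pair(a, b)


class TestRmsdMatrix:
    def test_identical_models_zero_matrix(self):
        m = cloud_model(np.random.default_rng(2).normal(size=(6, 3)))
        dm = rmsd_matrix([m, m.copy()], labels=["a", "b"])
        np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)

    def test_symmetric_zero_diagonal(self, dodecamer_subunits):
        dm = rmsd_matrix(dodecamer_subunits[:3], Selection(preset="CA"), labels=list("ABC"))
        np.testing.assert_allclose(dm.d, dm.d.T)
        np.testing.assert_allclose(np.diag(dm.d), 0.0)

    def test_invariant_under_common_rigid_transform(self, dodecamer_subunits):
        models = dodecamer_subunits[:4]
        R = rs.structure_io.rotation_about_axis((1, 2, 3), 77.0)
        t = np.array([5.0, -3.0, 11.0])
        moved = [m.transformed(R, t) for m in models]
        d0 = rmsd_matrix(models, Selection(preset="CA"), labels=list("ABCD")).d
        d1 = rmsd_matrix(moved, Selection(preset="CA"), labels=list("ABCD")).d
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestMeanReference:
    def test_single_model_returns_itself(self):
        m = cloud_model(np.random.default_rng(3).normal(size=(5, 3)))
        res = mean_reference([m])
        assert res.n_iterations == 1 and res.converged
        np.testing.assert_allclose(res.model.coords(), m.coords())

    def test_two_rotated_models_equidistant_from_mean(self):
        coords = np.random.default_rng(4).normal(size=(8, 3)) * 2.0
        a = cloud_model(coords)
        R = rs.structure_io.rotation_about_axis((0, 1, 0), 25.0)
        b = cloud_model(coords @ R.T)
        res = mean_reference([a, b], tol=1e-10)
        ra = superpose_pair(a, res.model).rmsd
        rb = superpose_pair(b, res.model).rmsd
        assert abs(ra - rb) < 1e-6

    def test_noisy_ring_converges_quickly(self):
        ring = rs.make_ring(rs.RingSpec(n_subunits=12, noise_sigma=0.2, seed=1))
        subs = [select_atoms(ring, Selection(chains=(c,))) for c in ring.chain_ids()]
        res = mean_reference(subs, Selection(preset="CA"), max_iter=5, tol=1e-4)
        assert res.converged and res.n_iterations <= 5

    def test_objective_non_increasing(self, dodecamer_subunits):
        res = mean_reference(dodecamer_subunits, Selection(preset="CA"), tol=1e-12, max_iter=10)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-12)


TWO_BLOCK = DistanceMatrix(
    labels=["a1", "a2", "b1", "b2"],
    d=np.array([
        [0.0, 0.1, 1.0, 1.0],
        [0.1, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.1],
        [1.0, 1.0, 0.1, 0.0],
    ]),
)


class TestHierarchicalCluster:
    @pytest.mark.parametrize("linkage", ["complete", "ward"])
    def test_two_block_fixture_recovered(self, linkage):
        tree = hierarchical_cluster(TWO_BLOCK, linkage)
        groups = cut_tree(tree, 2)
        assert groups["a1"] == groups["a2"] != groups["b1"]
        assert groups["b1"] == groups["b2"]

    def test_two_items_single_merge_at_distance(self):
        dm = DistanceMatrix(labels=["x", "y"], d=np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = hierarchical_cluster(dm, "complete")
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.7)

    def test_nan_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(labels=list("abc"), d=d), "complete")

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [4, 6, 7])
    def test_complete_linkage_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(labels=[f"m{i}" for i in range(n)], d=d)
        tree = hierarchical_cluster(dm, "complete")
        np.testing.assert_allclose(sorted(tree.linkage_matrix[:, 2]),
                                   brute_force_complete_linkage(d), atol=1e-10)

    def test_dodecamer_two_rings_split(self, dodecamer_subunits):
        dm = rmsd_matrix(dodecamer_subunits, Selection(preset="main-chain"),
                         labels=list("ABCDEFGHIJKL"))
        for linkage in ("ward", "complete"):
            groups = cut_tree(hierarchical_cluster(dm, linkage), 2)
            assert len({groups[c] for c in "ABCDEF"}) == 1
            assert len({groups[c] for c in "GHIJKL"}) == 1
            assert groups["A"] != groups["G"]

    def test_newick_export_contains_all_leaves(self):
        tree = hierarchical_cluster(TWO_BLOCK, "complete")
        nw = tree.to_newick()
        assert nw.endswith(";")
        for label in TWO_BLOCK.labels:
            assert label in nw


class TestCutTree:
    def test_k1_single_group(self):
        tree = hierarchical_cluster(TWO_BLOCK, "complete")
        assert set(cut_tree(tree, 1).values()) == {0}

    def test_kn_singletons(self):
        tree = hierarchical_cluster(TWO_BLOCK, "complete")
        assert len(set(cut_tree(tree, 4).values())) == 4

    def test_out_of_range_raises(self):
        tree = hierarchical_cluster(TWO_BLOCK, "complete")
        with pytest.raises(ValueError):
            cut_tree(tree, 5)


class TestSimilarityEdges:
    def test_two_block_within_edges_heavier(self):
        edges = similarity_edges(TWO_BLOCK, levels=2)
        assert {frozenset(e[:2]) for e in edges} == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
        assert all(w == pytest.approx(10.0) for _, _, w in edges)

    def test_single_pair(self):
        dm = DistanceMatrix(labels=["x", "y"], d=np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert similarity_edges(dm, 1) == [("x", "y", 2.0)]

    def test_zero_distance_capped(self):
        dm = DistanceMatrix(labels=["x", "y"], d=np.zeros((2, 2)))
        assert similarity_edges(dm, 1)[0][2] == 1e6

    def test_dodecamer_heaviest_edges_within_rings(self, dodecamer_subunits):
        dm = rmsd_matrix(dodecamer_subunits, Selection(preset="CA"), labels=list("ABCDEFGHIJKL"))
        for u, v, _w in similarity_edges(dm, levels=6):
            same_ring = (u in "ABCDEF") == (v in "ABCDEF")
            assert same_ring


def _arg_residue(chi1_offset=0.0):
    """Minimal ARG-like residue; rotating CG about the CA–CB axis changes χ1."""
    base = {
        "N": [0.0, 1.4, 0.0],
        "CA": [0.0, 0.0, 0.0],
        "CB": [1.45, -0.55, 0.0],
        "CG": None,
        "CD": None,
    }
    from ringstack.synthetic_data import place_atom

    n, ca, cb = (np.array(base[k]) for k in ("N", "CA", "CB"))
    cg = place_atom(n, ca, cb, 1.52, 114.0, -65.0 + chi1_offset)
    cd = place_atom(ca, cb, cg, 1.52, 111.0, 180.0)
    coords = dict(base, CG=cg, CD=cd)
    atoms = [point_atom(i + 1, coords[name], name=name, res_seq=14, res_name="ARG",
                        element=name[0]) for i, name in enumerate(["N", "CA", "CB", "CG", "CD"])]
    return StructureModel(atoms=atoms)


class TestSidechainChiCompare:
    def test_identical_models_zero_differences(self):
        m = _arg_residue()
        rows = sidechain_chi_compare(m, m.copy(), [("A", 14)])
        assert rows[0]["d_chi1"] == pytest.approx(0.0, abs=1e-9)
        assert rows[0]["d_chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_rotated_chi1_reports_offset(self):
        rows = sidechain_chi_compare(_arg_residue(), _arg_residue(chi1_offset=120.0), [("A", 14)])
        assert abs(rows[0]["d_chi1"]) == pytest.approx(120.0, abs=1e-6)

    def test_missing_atoms_flagged_not_fatal(self):
        m = _arg_residue()
        truncated = StructureModel(atoms=[a.copy() for a in m.atoms if a.name != "CD"])
        rows = sidechain_chi_compare(m, truncated, [("A", 14), ("A", 99)])
        assert rows[0]["flagged"] and rows[0]["d_chi2"] is None
        assert rows[0]["d_chi1"] is not None
        assert rows[1]["flagged"]

    def test_circular_difference_wraps(self):
        assert circular_difference(170.0, -170.0) == pytest.approx(-20.0)
        assert circular_difference(-170.0, 170.0) == pytest.approx(20.0)
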