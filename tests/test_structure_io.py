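import numpy as np
import pytest

import ringstack as rs
from ringstack.structure_io import (
    AtomRecord,
    EmptySelectionWarning,
    PDBParseError,
    Selection,
    StructureModel,
    UnitCell,
    expand_rotational_symmetry,
    read_structure,
    select_atoms,
    write_structure,
)

from conftest import cloud_model, point_atom


class TestReadWrite:
    def test_reads_atom_and_hetatm_records(self, two_atom_pdb):
        model = read_structure(two_atom_pdb)
        assert len(model) == 2
        assert [a.is_het for a in model] == [False, True]
        assert model.atoms[0].element == "N"
        assert model.atoms[1].occupancy == 0.5
        assert model.cell == UnitCell(10.0, 12.0, 14.0, 90.0, 90.0, 90.0, "P 1")

    def test_two_atom_round_trip_preserves_fields(self, two_atom_pdb, tmp_path):
        model = read_structure(two_atom_pdb)
        out = tmp_path / "out.pdb"
        write_structure(model, out)
        back = read_structure(out)
        for a, b in zip(model, back):
            assert a.name == b.name and a.res_name == b.res_name
            assert a.chain_id == b.chain_id and a.res_seq == b.res_seq
            assert a.is_het == b.is_het
            np.testing.assert_allclose(a.xyz, b.xyz, atol=1.5e-3)
            assert a.occupancy == pytest.approx(b.occupancy, abs=5e-3)
            assert a.b_iso == pytest.approx(b.b_iso, abs=5e-3)

    def test_anisou_round_trip_uses_1e4_scale(self, tmp_path):
        u = (0.0123, 0.0456, 0.0789, 0.0011, -0.0022, 0.0033)
        model = StructureModel(atoms=[point_atom(1, (0, 0, 0), u_aniso=u)])
        path = tmp_path / "aniso.pdb"
        write_structure(model, path)
        line = next(l for l in path.read_text().splitlines() if l.startswith("ANISOU"))
        ints = [int(line[28 + 7 * k : 35 + 7 * k]) for k in range(6)]
        assert ints == [round(x * 1e4) for x in u]
        back = read_structure(path)
        np.testing.assert_allclose(back.atoms[0].u_aniso, u, atol=1e-4)

    def test_hexamer_round_trip_rmsd_zero_to_precision(self, tmp_path):
        ring = rs.make_ring(rs.RingSpec(seed=3, noise_sigma=0.1))
        path = tmp_path / "ring.pdb"
        write_structure(ring, path)
        back = read_structure(path)
        assert len(back) == 60
        assert np.abs(back.coords() - ring.coords()).max() <= 5.1e-4

    def test_parse_write_parse_fixed_point(self, tmp_path):
        ring = rs.make_ring(rs.RingSpec(seed=5, noise_sigma=0.2))
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(ring, p1)
        m1 = read_structure(p1)
        write_structure(m1, p2)
        m2 = read_structure(p2)
        np.testing.assert_array_equal(m1.coords(), m2.coords())

    def test_malformed_line_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM      1  N   ALA A   1      ######   6.134  -6.504  1.00 10.00\n")
        with pytest.raises(PDBParseError):
            read_structure(bad)

    def test_missing_model_raises(self, two_atom_pdb):
        with pytest.raises(FileNotFoundError):
            read_structure(two_atom_pdb, model_index=3)

    def test_empty_model_refuses_write(self, tmp_path):
        with pytest.raises(ValueError):
            write_structure(StructureModel(atoms=[]), tmp_path / "x.pdb")

    def test_negative_residue_numbers_preserved(self, tmp_path):
        # cleaved expression constructs number their vestigial tail ≤ 0
        atoms = [point_atom(i + 1, (float(i), 0, 0), name="CA", res_seq=i - 2) for i in range(4)]
        model = StructureModel(atoms=atoms)
        path = tmp_path / "neg.pdb"
        write_structure(model, path)
        assert [a.res_seq for a in read_structure(path)] == [-2, -1, 0, 1]


class TestValidation:
    def test_atom_invariants(self):
        with pytest.raises(ValueError):
            point_atom(1, (np.nan, 0, 0))
        with pytest.raises(ValueError):
            point_atom(1, (0, 0, 0), occupancy=1.5)
        with pytest.raises(ValueError):
            point_atom(1, (0, 0, 0), u_aniso=(-0.1, 0.1, 0.1, 0, 0, 0))

    def test_unit_cell_invariants(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 10, 10, 90, 90, 90)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 190, 90, 90)

    def test_duplicate_atom_identity_rejected(self):
        a = point_atom(1, (0, 0, 0))
        b = point_atom(2, (1, 0, 0))
        b.res_seq = a.res_seq
        with pytest.raises(ValueError, match="duplicate"):
            StructureModel(atoms=[a, b])


class TestSymmetryExpansion:
    def test_fold_one_is_identity(self):
        m = cloud_model([[1, 0, 0], [2, 1, 0]])
        out = expand_rotational_symmetry(m, 1)
        np.testing.assert_array_equal(out.coords(), m.coords())

    def test_twofold_about_z(self):
        m = cloud_model([[1.0, 0.0, 0.0]])
        out = expand_rotational_symmetry(m, 2, axis=(0, 0, 1))
        np.testing.assert_allclose(sorted(out.coords()[:, 0]), [-1.0, 1.0], atol=1e-12)
        assert len(out) == 2
        assert len(set(a.chain_id for a in out)) == 2

    @pytest.mark.parametrize("fold", [3, 6])
    def test_output_invariant_under_further_rotation(self, fold):
        m = cloud_model(np.random.default_rng(0).normal(size=(5, 3)) + [4, 0, 0])
        out = expand_rotational_symmetry(m, fold, axis=(0, 0, 1))
        assert len(out) == fold * len(m)
        R = rs.structure_io.rotation_about_axis((0, 0, 1), 360.0 / fold)
        rotated = out.coords() @ R.T
        # set-wise match to 1e-6 Å
        from scipy.spatial import cKDTree

        d, _ = cKDTree(out.coords()).query(rotated)
        assert d.max() < 1e-6

    def test_off_axis_origin(self):
        m = cloud_model([[2.0, 0.0, 0.0]])
        out = expand_rotational_symmetry(m, 2, axis=(0, 0, 1), origin=(1.0, 0.0, 0.0))
        np.testing.assert_allclose(sorted(out.coords()[:, 0]), [0.0, 2.0], atol=1e-12)

    def test_chain_label_exhaustion(self):
        m = cloud_model([[1, 0, 0]])
        with pytest.raises(ValueError, match="exhausted"):
            expand_rotational_symmetry(m, 70)


class TestSelection:
    @pytest.fixture()
    def tripeptide(self):
        atoms = []
        serial = 0
        for res in range(1, 4):
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")):
                serial += 1
                atoms.append(point_atom(serial, (serial, 0, 0), name=name, element=el,
                                        res_seq=res, res_name="ALA"))
        return StructureModel(atoms=atoms)

    def test_ca_preset(self, tripeptide):
        assert len(select_atoms(tripeptide, Selection(preset="CA"))) == 3

    def test_main_chain_counts_four_per_residue(self):
        atoms = []
        serial = 0
        for res in range(1, 69):
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")):
                serial += 1
                atoms.append(point_atom(serial, (serial * 0.1, res, 0), name=name,
                                        element=el, res_seq=res))
        model = StructureModel(atoms=atoms)
        sel = select_atoms(model, Selection(preset="main-chain", res_range=(1, 68)))
        assert len(sel) == 272

    def test_selection_idempotent(self, tripeptide):
        q = Selection(preset="main-chain", res_range=(1, 2))
        once = select_atoms(tripeptide, q)
        twice = select_atoms(once, q)
        assert [a.key for a in once] == [a.key for a in twice]

    def test_chain_range_parsing(self):
        assert Selection.parse_chains("A-F") == tuple("ABCDEF")
        assert Selection.parse_chains("A,C,E") == ("A", "C", "E")
        assert Selection.parse_chains("AF") == ("A", "F")

    def test_empty_selection_warns(self, tripeptide):
        with pytest.warns(EmptySelectionWarning):
            out = select_atoms(tripeptide, Selection(chains=("Z",)))
        assert len(out) == 0

    def test_het_filter(self, two_atom_pdb):
        model = read_structure(two_atom_pdb)
        assert len(select_atoms(model, Selection(het=True))) == 1
        assert select_atoms(model, Selection(het=False)).atoms[0].name == "N"

    def test_het_inventory(self, two_atom_pdb):
        assert read_structure(two_atom_pdb).het_inventory() == {"HOH": 1}
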