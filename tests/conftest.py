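import numpy as np
import pytest

import ringstack as rs
from ringstack.structure_io import AtomRecord, StructureModel, Selection, select_atoms

# standard synthetic dodecamer conditions: sub-0.3 Å mean pairwise RMSD,
# two ring-conformer populations, Δ=4°, δ=1.5°, rise 33 Å
DODECAMER_SPEC = rs.StackSpec(
    ring=rs.RingSpec(n_subunits=6, radius=22.0, noise_sigma=0.1, seed=7),
    delta_deg=4.0,
    tilt_deg=1.5,
    rise=33.0,
    flip_second_ring=True,
    ring_b_perturbation=0.2,
)
DODECAMER_CHAINS = tuple("ABCDEFGHIJKL")

# ANM cutoff matched to the 10-point surrogate's node spacing (the 15 Å
# default presumes real ~3.8 Å CA spacing)
SURROGATE_ANM_CUTOFF = 30.0


def point_atom(serial, xyz, name="CA", chain="A", res_seq=None, element="C",
               res_name="GLY", is_het=False, **kw):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc="", res_name=res_name,
        chain_id=chain, res_seq=res_seq if res_seq is not None else serial, i_code="",
        xyz=np.asarray(xyz, float), is_het=is_het, **kw,
    )


def cloud_model(coords, chain="A", element="C", name="CA", is_het=False):
    """Point-cloud model: one CA-style atom per coordinate row."""
    return StructureModel(atoms=[
        point_atom(i + 1, c, name=name, chain=chain, element=element, is_het=is_het)
        for i, c in enumerate(np.asarray(coords, float))
    ])


@pytest.fixture(scope="session")
def dodecamer():
    return rs.make_stacked_rings(DODECAMER_SPEC)


@pytest.fixture(scope="session")
def dodecamer_subunits(dodecamer):
    return [select_atoms(dodecamer, Selection(chains=(c,))) for c in DODECAMER_CHAINS]


@pytest.fixture()
def two_atom_pdb(tmp_path):
    path = tmp_path / "two_atoms.pdb"
    path.write_text(
        "CRYST1   10.000   12.000   14.000  90.00  90.00  90.00 P 1           1\n"
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N\n"
        "HETATM    2  O   HOH B 101       2.000   3.000   4.000  0.50 20.00           O\n"
        "END\n"
    )
    return path
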