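"""Crystallographic bookkeeping: cell volume, Matthews coefficient,
solvent content, sequence mass and the data-to-parameter ratio.

Uses the printed unit cells of the two crystal forms of the hexameric
ring assembly: a triclinic cell holding a stacked dodecamer (Z = 12)
and a hexagonal cell holding one subunit per asymmetric unit (Z = 6
copies per cell).
"""

from ringstack.crystal_calc import cell_volume, matthews, protein_mass, reflections_per_atom
from ringstack.structure_io import UnitCell

p1 = UnitCell(63.46, 66.06, 66.10, 60.05, 83.94, 77.17, "P 1")
p6 = UnitCell(66.19, 66.19, 34.21, 90.0, 90.0, 120.0, "P 6")
monomer = 9482.9  # Da, from the 83-residue cleaved construct

for name, cell, z in (("P1 (dodecamer)", p1, 12), ("P6 (hexamer)", p6, 6)):
    res = matthews(cell, z, monomer)
    print(f"{name}: V = {cell_volume(cell):.3e} A^3, "
          f"V_M = {res.v_m:.2f} A^3/Da, solvent = {100*res.solvent_fraction:.2f} %")

print(f"\nglycine peptide check: mass('GG') = {protein_mass('GG'):.2f} Da")
tag = "MGSSHHHHHHSSGLVPR"
print(f"thrombin-removed tag fragment mass: "
      f"{protein_mass(tag + 'G') - protein_mass('G'):.1f} Da")
print(f"reflections per atom (138120 / 8350): {reflections_per_atom(138120, 8350)}")

# V_M ~ 2.0-2.3 A^3/Da is the typical protein-crystal range; ~16.5
# reflections per atom makes individual anisotropic B refinement
# defensible (roughly twofold overdetermined)
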