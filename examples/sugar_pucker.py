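"""Nucleotide conformation: glycosidic torsion and sugar pucker.

Builds uridine nucleosides in the two conformations seen for the bound
RNA in the crystallized complex — a canonical North C3'-endo sugar and
a less common South C2'-endo one — and re-measures χ and the
pseudorotation phase P from the coordinates.
"""

import ringstack as rs
from ringstack.na_geometry import glycosidic_chi, pseudorotation, residue_view

for label, P_req, chi_req in (("U1", 17.5, -165.2), ("U2", 163.2, -116.8)):
    model = rs.make_sugar_ring(P_deg=P_req, nu_max=38.0, chi_deg=chi_req)
    view = residue_view(model)
    chi = glycosidic_chi(view)
    pk = pseudorotation(view)
    print(f"{label}: chi = {chi.chi:7.1f} deg ({chi.conformer}),  "
          f"P = {pk.P:6.1f} deg, nu_max = {pk.nu_max:.1f} deg "
          f"-> {pk.pucker_class} ({pk.hemisphere})")

# |chi| >= 90 deg is the anti range typical of pyrimidines bound in
# extended pockets; P near 18 deg is the A-form-like North pucker,
# P near 162 deg the South pucker more common in DNA
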