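"""Inter-ring rotation and tilt of a stacked double ring.

Generates a head-to-tail stack with known rotation Δ = 4°, tilt
δ = 1.5° and rise 33 Å, then recovers those parameters purely from the
coordinates via best-fit ring planes and subunit-azimuth phases.
"""

import ringstack as rs
from ringstack.structure_io import Selection, select_atoms

spec = rs.StackSpec(ring=rs.RingSpec(noise_sigma=0.0), delta_deg=4.0,
                    tilt_deg=1.5, rise=33.0)
stack = rs.make_stacked_rings(spec)

ring_a = select_atoms(stack, Selection(chains=tuple("ABCDEF")))
ring_b = select_atoms(stack, Selection(chains=tuple("GHIJKL")))
geo = rs.stack_geometry(ring_a, ring_b, n_fold=6)

print(f"in-plane rotation delta = {geo.delta_deg:.2f} deg  (generated: 4.00)")
print(f"inter-ring tilt  delta  = {geo.tilt_deg:.2f} deg  (generated: 1.50)")
print(f"rise along ring normal  = {geo.rise:.2f} A    (generated: 33.00)")

# delta is the azimuthal offset between the two rings' C6 phases, folded
# into (-30 deg, 30 deg]; tilt is the angle between the ring-plane
# normals.  Zero noise -> exact recovery to numerical precision.
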