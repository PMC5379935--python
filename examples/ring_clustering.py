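"""Subunit RMSD matrix and hierarchical clustering of a double ring.

Builds a synthetic head-to-tail stacked dodecamer whose two rings carry
slightly different subunit conformations (plus coordinate noise),
computes all 66 pairwise main-chain superposition RMSDs, and clusters
the 12 chains.  With realistic noise the mean pairwise RMSD stays below
0.3 Å yet the two ring populations still separate cleanly at k = 2.
"""

import ringstack as rs
from ringstack.structure_io import Selection, select_atoms
from ringstack.superpose_cluster import cut_tree, hierarchical_cluster, rmsd_matrix

spec = rs.StackSpec(
    ring=rs.RingSpec(n_subunits=6, radius=22.0, noise_sigma=0.1, seed=7),
    delta_deg=4.0, tilt_deg=1.5, rise=33.0, ring_b_perturbation=0.2,
)
stack = rs.make_stacked_rings(spec)
chains = stack.chain_ids()
subunits = [select_atoms(stack, Selection(chains=(c,))) for c in chains]

dm = rmsd_matrix(subunits, Selection(preset="main-chain"), labels=chains)
print(f"mean pairwise main-chain RMSD over {len(chains)*(len(chains)-1)//2} pairs: "
      f"{dm.mean_offdiag():.3f} A")

for linkage in ("ward", "complete"):
    tree = hierarchical_cluster(dm, linkage)
    groups = cut_tree(tree, 2)
    members = {g: [c for c, gg in groups.items() if gg == g] for g in set(groups.values())}
    print(f"{linkage:>8} linkage, k=2: " + "  |  ".join(
        "".join(m) for m in members.values()))

# the sub-0.3 A mean says the 12 subunits are nearly identical copies;
# the clean A-F / G-L split says the residual differences are systematic
# between the rings, not random noise
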