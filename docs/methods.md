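# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate model and I/O

Structures are flat, ordered atom lists grouped by chain and residue,
with coordinates in orthogonal Å (no fractional-coordinate math outside
the crystallographic module). PDB reading/writing is delegated to gemmi;
this package only maps records. Anisotropic displacement parameters are
kept on the absolute U scale (ANISOU integers ÷ 10⁴ Å²). Alternate
locations collapse to the highest-occupancy conformer by default
(`keep_alt_locs=True` retains all); multi-model files default to model 1;
residue numbering is preserved verbatim, including non-positive numbers
used for vestigial expression-tag residues. A pre-parse validation pass
rejects coordinate fields that do not parse as numbers, because the
underlying reader would otherwise silently zero them.

Rotational symmetry expansion produces `fold` copies rotated by
k·360°/fold about a given axis, with unique chain relabeling; it covers
pure rotations only (building a hexamer from one subunit about a 6-fold
axis), not general space-group operators.

## Superposition and clustering

Pairwise superposition is least-squares rigid-body fitting via SVD of
the covariance matrix, with the determinant-sign correction so that only
proper rotations are returned (mirror solutions are excluded; tests
verify agreement with an independent quaternion closed form to 10⁻⁸ Å).
Atoms are matched by (residue number, insertion code, atom name) within
a selection; mismatched sets are an error naming the first unmatched
atom, so silent partial matches cannot occur. "Main-chain" means
{N, CA, C, O}; a CA-only preset is also provided.

The mean-reference procedure alternates align-all-to-mean / average
until the mean moves less than `tol` (Å); the summed squared deviation
to the mean is non-increasing across iterations, and non-convergence at
`max_iter` is flagged rather than raised.

Hierarchical clustering consumes the RMSD matrix with scipy's
agglomerative linkage. Complete linkage uses the matrix as-is; Ward
treats it as if it were a Euclidean dissimilarity — a convention carried
over from common practice with conformer RMSD matrices, not a metric
guarantee. Leaves are pre-sorted by label so equal-height merges break
ties lexicographically and reruns are deterministic. Similarity edges
for network-style views are the `levels` smallest off-diagonal
distances, weighted 1/RMSD (capped at 10⁶ for zero distances).

Side-chain χ₁/χ₂ comparison uses the IUPAC atom quadruples; differences
are circular, in (−180°, 180°]; residues with missing atoms are flagged
per-residue, never fatal.

## Ring and stack geometry

Principal axes come from the unit-mass (optionally weighted) inertia
tensor about the centroid; moments are ascending and each axis's
largest component is made positive. Near-degenerate moment pairs
(relative gap < 10⁻⁶) are flagged — a planar C_n ring necessarily has a
degenerate in-plane pair. Best-fit planes come from SVD; the normal is
the least-variance direction, sign-fixed toward +z (then +y, +x).

The inter-ring rotation Δ of a stacked pair has no unique
coordinate-free definition for a C_n object, so the package defines it
operationally: each ring's subunit anchors (per-chain CA centroids)
are reduced to the phase ψ = arg(Σ_k exp(i·n·φ_k))/n of their azimuths
φ_k about the shared normal (ring B's anchors are first rotated by the
minimal rotation taking its plane normal onto ring A's), and
Δ = ψ_B − ψ_A folded into (−180°/n, 180°/n]. This order-parameter form
needs no subunit matching, is exactly invariant under a common rigid
transformation, and recovers the generating parameters of synthetic
stacks (including head-to-tail flipped rings, whose first subunit the
generator anchors at azimuth zero) to numerical precision. Tilt δ is
the angle between ring-plane normals folded to ≤ 90°; it agrees with
the angle between largest-moment inertia axes to well under 0.2° for
planar anchor sets. Rise is the centroid separation projected on ring
A's normal.

## Surface areas

SASA uses Shrake–Rupley surface-dot counting: each atom is covered with
a deterministic golden-spiral point set (not random — exact
reproducibility) on its solvent-expanded sphere (element vdW radius,
Bondi-style table, 1.70 Å fallback for table-absent elements; unknown
element symbols are an error naming the atom) and the accessible area
is the exposed-dot fraction times the sphere area. Neighbor search uses
a k-d tree; a naive all-pairs oracle in the tests confirms the pruning.
Quadrature error on an isolated sphere is < 0.5% at 960 dots; the
orientation dependence of totals is quadrature noise shrinking roughly
as 1/n_dots (≈ 0.4% at 960 dots, ≤ 0.1% at 3840 for a 15-atom cluster).

Buried surface area is BSA = ASA_A + ASA_B − ASA_AB on identical atom
sets. The consensus that multi-program comparisons provide is emulated
with an ensemble over dot densities (probe 1.4 Å; 320/640/960/1280/1920
dots) of this single algorithm, reported as mean ± SD — a deliberate,
dependency-free stand-in for running five different programs, which
captures quadrature-level method variance but not inter-algorithm
radius/definition differences. Heteroatoms are excluded from BSA by
default (ring–ring interfaces are protein-defined; lattice solvent and
ions are not part of them); `include_het=True` overrides.

## Elastic-network model

Nodes are CA atoms only. The Hessian uses the standard ANM
super-element: off-diagonal block −γ·(r_ij r_ijᵀ)/|r_ij|² for pairs
within the cutoff, diagonal blocks minus the row sum (block row sums
vanish to 10⁻¹⁰). Dense `scipy.linalg.eigh` returns the full ascending
spectrum (fine for ≤ ~1000 nodes). Zero modes are λ < 10⁻⁶·λ_max — a
scale-free threshold robust for γ = 1 networks; a connected,
mechanism-free network has exactly 6 (a two-node dumbbell has 5 and a
single nontrivial eigenvalue 2γ). Disconnected contact graphs warn with
the component count. Defaults γ = 1 (arbitrary units; eigenvalues scale
linearly in γ) and cutoff 15 Å are the conventional choices for real CA
networks at ~3.8 Å spacing. The 10-point synthetic subunits are ~6×
coarser, so analyses of generated assemblies use a 30 Å cutoff — the
smallest round value giving a single-component network with exactly six
zero modes for the standard synthetic dodecamer.

Counter-rotation content of a mode is the |cosine| overlap between the
unit-normalized mode vector and the unit-normalized antisymmetric rigid
rotation field (+ω×r on ring A nodes, −ω×r on ring B) about the stack
axis through the node centroid. On the standard synthetic dodecamer the
softest nontrivial mode carries overlap ≈ 0.9–0.97; the acceptance
threshold (> 0.5 among the 20 softest modes) was fixed from that
empirical run. This statistic is the package's quantification of a
motion that is otherwise judged by visual inspection.

B_eq = 8π²·tr(U)/3 converts ADP tensors; principal U values are the
eigenvalues of the symmetric U matrix, and a non-positive trace is
flagged rather than fatal.

## Nucleotide conformation and contacts

Torsions are signed IUPAC dihedrals in (−180°, 180°]. χ is
O4′–C1′–N1–C2 for pyrimidines, O4′–C1′–N9–C4 for purines; anti iff
|χ| ≥ 90°. Pseudorotation follows Altona–Sundaralingam with ν₂ as the
reference torsion: tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2ν₂(sin 36° + sin 72°)),
ν_max = ν₂/cos P, so C3′-endo sits near P = 18° and C2′-endo near 162°.
Classes come from the 20 standard 18° bins (envelopes at odd multiples
of 18°, twists at even ones); the hemisphere is the compass quadrant
(North [315°, 45°), East, South, West). Rings with ν_max < 5° are
amplitude-undefined and get no class.

Contacts are distance-only: all inter-group heavy-atom pairs within the
cutoff (default 3.6 Å), labeled hbond-candidate when both atoms are
N/O at ≤ 3.5 Å, else vdw. With no hydrogens in deposited structures no
angular term is possible; this is a screening heuristic, not an energy
model. π-stacking requires centroid distance ≤ 4.5 Å, inter-plane angle
≤ 30° and in-plane offset ≤ 2.5 Å (common-practice defaults, all
exposed as parameters); rings with plane RMS > 0.3 Å are flagged
non-planar.

## Crystallographic bookkeeping

Cell volume uses the triclinic closed form
V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosαcosβcosγ) (tested against
the metric-tensor determinant). V_M = V/(Z·M); solvent fraction
1 − 1.23/V_M with 1.23 Å³ Da⁻¹ from a partial specific volume of
0.74 cm³ g⁻¹ — this constant reproduces the printed solvent contents of
both crystal forms from their printed V_M inputs. Protein masses use
standard average (default) or monoisotopic residue tables plus one
water; the average table matches Biopython's to < 0.1 Da on test
sequences. The resolution-dependent Matthews probability is out of
scope; only the deterministic V_M is computed.

## Binding isotherms

The logistic model is a Boltzmann sigmoid in x = log₁₀[titrant]:
mP(x) = A2 + (A1 − A2)/(1 + exp((x − x0)/dx)), with A1 the zero-binding
baseline, A2 the saturation plateau, x0 = log₁₀ K_d,app and dx the
transition width in decades; the Hill coefficient is reported as
n_H = 1/(dx·ln 10). The depletion model is the exact 1:1 quadratic for
the bound fraction of the fixed species,
f = (T + L + K_d − √((T + L + K_d)² − 4TL))/(2L) with L the probe
total, mapped to mP = A1 + (A2 − A1)·f. Its half-saturation point is at
T = K_d + L/2, so fitting the logistic to depletion-generated data
yields an apparent K_d exceeding the true one by half the fixed
species' total — the offset `compare_fits` reports for context. (The
offset is stated in terms of the fixed-probe total because that is the
mathematically exact consequence of the quadratic model.)

Fits are unweighted nonlinear least squares over replicate-level points
(lmfit; `average_replicates=True` fits means instead). Initial guesses:
plateaus from the extreme concentration quartiles, midpoint from the
half-height crossing. Concentrations are molar in the titrated
oligomer; callers titrating per-monomer concentrations of an n-mer
should divide by n on input. Standard errors come from the lmfit
covariance; a transition not bracketed by the data warns.

## Synthetic data: what it does and does not emulate

Rings are n rotational copies (default n = 6, radius 22 Å) of a rigid,
internally asymmetric 10-point cloud, with i.i.d. per-coordinate
Gaussian noise; all generators are pure functions of (spec, seed).
Stacks apply, in order, optional head-to-tail flip (180° about x),
rotation Δ about z, tilt δ about x (the two rotations do not commute;
this order is the definition), and translation by the rise. An optional
`ring_b_perturbation` applies one common template deformation to every
ring-B subunit, creating the two internally homogeneous conformer
populations that a real stacked dodecamer shows; without it,
identical-template rings cannot reproduce population-level clustering.
The standard synthetic dodecamer used in tests and in the acceptance
script is σ = 0.1 Å noise with a 0.2 Å ring-B perturbation, Δ = 4°,
δ = 1.5°, rise 33 Å — conditions chosen to land in the regime of
near-identical subunits (mean pairwise main-chain RMSD < 0.3 Å) that
still cluster cleanly by ring.

The expected pairwise RMSD between noisy subunit copies is
σ·√(2(3N−6)/N) after removing the six fitted rigid-body degrees of
freedom (≈ 2.14σ for N = 10; the frozen Monte-Carlo oracle value is
0.428 Å at σ = 0.2).

Nucleosides are built by sequential natural-extension placement of the
furanose with standard bond lengths/angles, followed by a short
least-squares refinement of the five ring atoms against the target
endocyclic torsions (weighted heavily) plus bonds/angles; ring-closure
residuals above 0.1 Å are an error, and requested P round-trips within
0.4° in practice (2° tolerance asserted). The uracil base is attached
planar with the requested χ. FP titrations evaluate the chosen model on
the concentration grid and add Gaussian mP noise per replicate.

None of this is physically realistic protein structure: point-cloud
subunits have no secondary structure, side chains, packing or solvent,
so passing tests demonstrate the correctness of the geometry,
clustering, surface, mode and fitting machinery — not biological
conclusions about any particular assembly. Analyses of real deposited
coordinates use the same code paths but their numerical results depend
on inputs this repository does not ship.

## Problem sizes and determinism

The full test suite runs in well under a minute on one CPU: the
standard dodecamer has 120 atoms/nodes (ANM 360×360 dense eigensolve),
SASA fixtures are ≤ 15 atoms at ≤ 3840 dots, and the stochastic binding
calibration uses 200 seeded titrations of 18 × 3 points. The
acceptance script finishes in a few seconds and derives every random
stream from its `--seed` argument; reruns with the same seed are
byte-identical.
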