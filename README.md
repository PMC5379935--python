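# ringstack

Quantitative structural analysis of cyclic homo-oligomer rings and their
stacked double-ring assemblies — the kind of quaternary architecture formed
by Sm-fold RNA chaperones such as bacterial Hfq, whose hexameric toroids
stack head-to-tail into dodecamers and bind single-stranded RNA at several
distinct surfaces.

The package is aimed at structural biologists who have (or simulate)
coordinates of such assemblies and want reproducible numbers for:

* **Subunit comparison** — least-squares rigid superposition (Kabsch/SVD,
  proper rotations only), all-pairs main-chain RMSD matrices, iterative
  mean-reference alignment, and agglomerative clustering (complete linkage
  or Ward on the RMSD matrix) to detect distinct conformer populations;
* **Ring-stack geometry** — best-fit ring planes and inertia axes; the
  inter-ring in-plane rotation Δ (difference of the rings' C<sub>n</sub>
  azimuthal order-parameter phases, folded into (−180°/n, 180°/n]), the
  tilt δ between ring normals, and the rise along the stack axis;
* **Surface burial** — Shrake–Rupley surface-dot SASA with deterministic
  golden-spiral quadrature, and the interface area
  BSA = ASA<sub>A</sub> + ASA<sub>B</sub> − ASA<sub>AB</sub> reported as a
  mean ± SD over an ensemble of dot densities;
* **Collective motions** — anisotropic network model (ANM) normal modes of
  the Cα network (spring constant γ, distance cutoff), with a cosine-overlap
  statistic quantifying how much a mode is an antisymmetric counter-rotation
  of the two rings; plus B<sub>eq</sub> = 8π²·tr(U)/3 from anisotropic ADPs;
* **Nucleotide conformation** — glycosidic torsion χ with syn/anti
  classification, furanose pseudorotation phase P and amplitude ν<sub>max</sub>
  (Altona–Sundaralingam convention, C3′-endo ≈ 18°, C2′-endo ≈ 162°),
  protein⋯RNA contact tables and a π-stacking test;
* **Crystallographic bookkeeping** — triclinic cell volume, Matthews
  coefficient V_M = V/(Z·M) and solvent content 1 − 1.23/V_M, protein mass
  from sequence, reflections-per-atom ratios;
* **Binding isotherms** — fluorescence-polarization titrations
  (P = (I∥ − I⊥)/(I∥ + I⊥), in mP) fitted with a four-parameter logistic in
  log₁₀[titrant] (Hill width dx, n_H = 1/(dx·ln 10)) or with the exact
  single-site quadratic that accounts for depletion of the fixed probe;
  neglecting depletion inflates the apparent K_d by probe_total/2, which the
  model comparison reports.

A first-class `synthetic_data` module generates C6 rings and stacked double
rings with controllable Δ/δ/rise and Gaussian noise, nucleosides with a
requested pucker and χ, and FP titrations from either binding model — so
every analysis is testable end-to-end with known ground truth and no
external downloads.

## Worked example

```bash
python examples/binding_fit.py
```

```
true K_d:                 10.00 nM (probe 5.0 nM)
depletion-model fit:      9.93 nM
logistic apparent K_d:    12.37 nM (Hill n_H = 1.10)
apparent minus true:      2.37 nM (predicted offset probe/2 = 2.50 nM)
depletion K_d lower by:   19.7 %
```

A 5 nM fluorescent probe titrated with a receptor of true K_d = 10 nM is
simulated with the exact quadratic isotherm and fitted both ways: the
depletion-aware fit recovers the true constant, while the logistic apparent
K_d is inflated by almost exactly half the probe concentration — the
systematic bias the depletion correction exists to remove.

```bash
python examples/ring_clustering.py
```

```
mean pairwise main-chain RMSD over 66 pairs: 0.272 A
    ward linkage, k=2: ABCDEF  |  GHIJKL
complete linkage, k=2: ABCDEF  |  GHIJKL
```

Twelve subunits of a synthetic stacked dodecamer are nearly identical
(mean pairwise RMSD < 0.3 Å), yet clustering still separates the two rings
exactly — the residual differences are systematic between rings, not noise.

The other scripts in `examples/` demonstrate stack-geometry recovery,
surface burial against an analytic oracle, ANM counter-rotation modes,
sugar-pucker round trips and crystallographic bookkeeping, one capability
per file. A thin `ringstack` command-line interface wraps the same library
calls (`ringstack info`, `simulate`, `cluster`, `geometry`, `sasa`, `bsa`,
`anm`, `na`, `contacts`, `matthews`, `mass`, `fit`, `run`).

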