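# Methods

This note records the models implemented, the default parameters and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions a user relying on the outputs should know.

## Grid-field descriptors

Aligned molecules are embedded in a minimal axis-aligned lattice covering
every atom plus a padding margin (defaults: 2.0 Å spacing, 4.0 Å padding).
Lattice points are ordered C-style with the z index fastest; all
coordinates are in Å throughout.

**CoMFA.** At every lattice point a probe atom — sp³ carbon, charge
+1.0 e, R\* = 1.70 Å, ε = 0.107 kcal/mol — interacts with the molecule:

- steric: 12-6 Lennard-Jones, `ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]` with
  `R_ij = R*_probe + R*_i` and `ε_ij = √(ε_probe ε_i)`. Per-element R\*/ε
  come from a bundled Tripos-style table.
- electrostatic: Coulomb with distance-dependent dielectric ε(r) = r
  (k_e = 332.0636 kcal·Å/(mol·e²)); a constant-dielectric mode is
  selectable.

Both fields are capped at ±30 kcal/mol (the conventional default; the cap
is configurable). Points whose steric energy reaches the positive cap lie
inside the molecule; the electrostatic values there carry no physical
information and are replaced by the training-set column mean over
unmasked molecules — the standard within-cap masking. An atom sitting
exactly on a lattice point contributes the capped value rather than a
division error.

Partial charges are iterative Gasteiger charges (PEOE, 6 damped
iterations). This is a deliberate, documented substitution for
Gasteiger–Hückel charges, whose π-component depends on proprietary
parameterization; plain Gasteiger is reproducible from published tables
and is verified in the tests against a hand-iterated reference for water.

**CoMSIA.** Similarity indices
`A_k(j) = −Σᵢ w_probe,k · w_ik · exp(−α r²_ij)` with attenuation
α = 0.3 Å⁻² (Klebe's published default; configurable) and probe weights 1
for all five properties. Atom properties: steric `r³_vdW`; electrostatic
the partial charge; hydrophobic +1 for carbons/halogens without N/O
neighbours, −1 for polar atoms; donor 1 for hydrogens on N/O; acceptor 1
for N/O without positive formal charge. These are simple auditable rules,
not a claim of matching any proprietary typing scheme.

**Design matrix.** Columns with training standard deviation below a
minimum sigma are dropped (2.0 kcal/mol for CoMFA energies; 0.0 for the
small-magnitude CoMSIA indices). Each field block is then scaled to unit
total variance so no field dominates a priori. All masking, filtering and
scaling statistics are fitted on training molecules only and frozen for
test/query molecules — and are refitted inside every cross-validation
fold, so no information leaks into q² or r²_pred.

## Alignment and splitting

Each molecule's scaffold match (substructure query, SMARTS) is rigidly
superposed onto the template's scaffold by the Kabsch algorithm (proper
rotation, det = +1). Among multiple matches the lowest post-fit RMSD
wins; exact ties break on the lexicographically smallest atom-index
tuple, making alignment deterministic. Molecules without a match are
excluded and reported, not silently dropped. With fewer than three
non-collinear matched atoms the rotation is not unique; the implementation
still returns an RMSD-optimal proper rotation, which is the quantity the
alignment and the RMSD metrics actually need. Geometries with all z = 0
are rejected as 2D: grid fields are meaningless without 3D structure.

The train/test split is a seeded random partition with the template
forced into the training set.

## PLS regression and validation

NIPALS PLS1 with X (and y) deflation; for a single response every
component is a closed-form pass, so the fit is deterministic and needs no
iteration tolerance. Coefficients for a k-component truncation are
`B_k = W_k(P_k'W_k)⁻¹q_k`. X is centered only (block scaling lives in the
assembly step); y is centered, never autoscaled. Rank exhaustion
truncates the component count with a warning.

- q² = 1 − PRESS_cv/SS_tot from leave-one-out CV; the optimal N is the
  argmax of the q² profile over 1..min(15, n/5) components, ties to the
  smaller N.
- r² = 1 − SS_res/SS_tot on the final fit; SEE = √(SS_res/(n−N−1)); the
  CV-flavoured SEE uses PRESS in place of SS_res (PRESS-based by choice —
  both are computable, this one needs no refit bookkeeping).
- F = (r²/N)/((1−r²)/(n−N−1)) on the non-cross-validated fit; a perfect
  fit reports an infinite-F sentinel.
- Field contributions: `Σ_j |b_j|·sd(X_j)` per field, normalized to 1.
- External validation: r²_pred = (SD − Press)/SD with SD the sum of
  squared deviations of the test activities **from the training mean**
  (the standard convention; a flag switches to the test mean).

y-scrambling is available as a negative control: the median LOO q² over
permuted activities should drop to ≤ 0.

## Contour maps

The display quantity is StDev*Coeff: training column standard deviation
times the PLS coefficient, with filtered columns carrying a neutral 0.
Favored/disfavored levels are the 80th percentile of positive and the
20th percentile of negative contributions (linear-interpolation
percentiles; both configurable) — a display convention, since absolute
contour levels are not physically meaningful. Grids export as OpenDX text.

## Trajectory metrics

Internal units are Å; reports can emit nm where that is customary for
RMSD/Rg plots. Default RMSD/RMSF selection is the protein backbone
(N, CA, C, O), configurable; RMSF superposes frames onto the iterated
time-average structure and aggregates residues by a mass-weighted mean.
Trajectories are assumed whole/unwrapped; a bond-length heuristic warns
when input looks wrapped. No periodic imaging is applied.

Hydrogen bonds use the geometric criterion: heavy-donor–acceptor distance
< 3.5 Å AND the angle at the hydrogen (donor-H…acceptor) > 135°. The
angle is read at the hydrogen — the only chemically standard
interpretation of a donor–H–acceptor angle. Both inequalities are strict:
a pair exactly at a cutoff is a non-event. Hydrophobic contacts
(apolar-carbon pairs < 4.0 Å across the protein/ligand partition) and
salt bridges (oppositely signed charge-group centroids < 5.5 Å) follow
the PLIP-style defaults and are configurable.

## Essential dynamics

Covariance of the Cartesian coordinates of the selected atoms (Cα by
default) after iterated superposition onto the mean structure (2 passes).
Eigenvectors are orthonormal with a deterministic sign convention (the
largest-magnitude element positive). The DCCM normalizes per-residue
displacement covariances into [−1, 1]; zero-variance residues are masked
with a warning rather than silently set.

The free-energy landscape is −kT·ln(P/P_max) over a 2D histogram of the
first two projections (32×32 bins, T = 300 K; output in kT with a
kcal/mol conversion). Empty bins are masked; minima are 8-neighbourhood
local minima ranked by depth then occupancy, so "minima[0]" is the global
basin. Porcupine arrows are the chosen eigenvector scaled by the signed
projection change between the two extreme frames in chronological order —
this keeps arrow lengths equal to the real motion amplitude and flips
only the sign when a trajectory is reversed.

## Binding energetics

Single-trajectory approximation: the complex geometry is reused for the
unbound partners, so intra-partition terms cancel and all MM and polar
terms reduce to protein–ligand cross sums. Conventions: LJ 12-6 with
`R_ij = R*_i + R*_j`, Coulomb with dielectric 1, k_e = 332.0636.

Solvation splits into a nonpolar term γ·SASA with γ = 0.00542
kcal/(mol·Å²) and no offset, and a polar term. The polar model is a
pairwise generalized-Born-style screening
`−k_e(1 − 1/ε_w) Σ q_i q_j / f_GB(r)` with
`f_GB = √(r² + R_iR_j·e^{−r²/4R_iR_j})`, Born radii taken as the vdW R\*,
ε_w = 78.5. A finite-difference Poisson–Boltzmann solver is deliberately
out of scope; the GB-like term preserves the equation structure (every
reported ΔG satisfies the additive chain identities per frame, asserted
at 1e-9) while remaining transparent. `polar_model="off"` disables it.
The entropy term −TΔS is carried as an explicit field fixed at 0
("neglected"), so report shapes match the conventional table layout.

SASA is Shrake–Rupley with a deterministic Fibonacci sphere (960 points,
probe 1.4 Å); doubling the point count changes totals by < 0.5% on the
test scenes. Averaging uses the final 10% of frames by default (the
standard "last segment of the production run" convention, `window`
configurable). The per-residue decomposition assigns each cross pair's MM
+ polar energy half to each partner residue and each atom's γ·ΔSASA to
its own residue, so contributions sum exactly to the decomposable total;
residues at or below −1 kcal/mol are flagged hot spots. (The sign
convention is "favorable = more negative"; the cutoff is a *≤ −1*
threshold.)

## Synthetic data: what it shows and what it does not

`gen_qsar_set` builds an isoxazole–phenyl scaffold with exact shared
geometry (phenyl tilted 30° out of the isoxazole plane, so molecules are
genuinely 3D) decorated at four ring positions from a six-substituent
menu (H, F, Cl, CH3, OH, NH2). The default conditions are 245 molecules,
203/42 split, activities spanning 6–10 pEC50, noise σ = 0.2 pEC50. The
noiseless activity is an exact linear function of 16 high-variance steric
field columns computed by the package's own field code on the
canonical-pose reference grid — so the planted signal travels through the
real alignment → fields → PLS chain, not a shortcut. Molecules are
emitted in random rigid poses (the template in canonical pose) with
coordinates rounded to SDF precision (1e-4 Å), which makes written files
re-read losslessly at the cost of ~1e-4 Å alignment residuals.

`gen_trajectory` plants sinusoidal modes on helix residues (correlated
pairs share a mode sign, anticorrelated pairs oppose), optional Gaussian
jitter, and a static interaction scene whose hydrogen bond, salt bridge
and hydrophobic contact satisfy the detection criteria by construction,
next to decoys that each violate exactly one criterion. Trajectory
coordinates are rounded to 1e-3 Å (PDB precision). `gen_complex` emits
random protein–ligand scenes (minimum cross-separation 3 Å) together with
an independent brute-force pair-loop energy sheet used as the oracle.

What passing tests demonstrate: the descriptor, regression,
cross-validation, detection and energy machinery is numerically correct
and recovers planted structure under realistic noise. What they do not
demonstrate: performance on real congeneric series (conformational
flexibility, tautomers, charge-model error), real MD ensembles
(anharmonicity, solvent, periodic artifacts), or agreement with
Poisson–Boltzmann solvation — none of which the generators emulate.

## Problem sizes and determinism

Default test-scale conditions are 60 molecules and 500-frame
trajectories; the full 245-molecule study conditions run in the
acceptance pipeline (a few seconds end to end). Every stochastic step
takes an explicit seed and is reproducible bit-for-bit; the acceptance
script threads one seed through generation, posing and splitting.

## Known limitations

- MOL2 reading supports the common multi-molecule concatenation but
  relies on RDKit's Tripos parser; exotic atom types may not map.
- Element parameters cover H/C/N/O/F/P/S/halogens; other elements fall
  back to carbon with a warning.
- The GB-like polar term uses fixed Born radii (vdW R\*); it is a
  screening model, not a solver, and its absolute values should not be
  compared against PB results.
- No conformer generation, tautomer handling, flexible alignment, region
  focusing, or normal-mode entropy — all out of scope by design.
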