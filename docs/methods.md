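# Methods

## Molecule and coordinate conventions

L-glutamate is treated as its 10 heavy atoms (N, CA, C, O1, O2, CB, CG,
CD, OE1, OE2), an acyclic tree of 9 bonds. The main-chain carboxylate
oxygens are named O1/O2 (wwPDB `O`/`OXT`); a translation table reconciles
deposited names on input. Torsions follow the IUPAC convention (cis = 0,
right-hand sign about the central bond) on (−180°, 180°]. Because a free
amino acid has no φ/ψ, the rotatable set is {χ₁, χ₂, χ₃, θ} with
θ = N-CA-C-O1 the single main-chain carboxyl torsion; the set is
configurable.

A complete internal-coordinate set is 24 numbers (3N − 6): 9 bonds,
8 angles and 7 dihedrals — the four named torsions, the two partner
carboxylate dihedrals (N-CA-C-O2 and CB-CG-CD-OE2), and one improper
(CB-CA-C-N) whose sign fixes the CA chirality. L-configuration is
enforced as a positive signed volume det(N−CA, C−CA, CB−CA); the default
improper of +122° realises it. Cartesian reconstruction is a NeRF chain
in the fixed order N, CA, C, O1, O2, CB, CG, CD, OE1, OE2 (N at origin,
CA on +x, C in the xy-plane); build∘measure round-trips to ≤ 1e-6 and
construction angles of 0/180° raise a degenerate-frame error. When a
named carboxyl torsion (θ or χ₃) is set programmatically, the partner
oxygen dihedral co-rotates so the O-C-O plane is preserved.

## Superposition and RMSD

Superposition is the Kabsch least-squares proper rotation (SVD with
determinant correction; reflections excluded to preserve chirality),
cross-checked in the tests against an independently implemented
quaternion-eigenvalue (Horn) oracle. `rmsd_symmetric` optionally takes
the minimum over the four relabelings generated by O1↔O2 and OE1↔OE2:
the swap is ON wherever chemically identical molecules are compared
(deduplication, synthetic ensembles) and OFF for the deposited-name
main-chain metric. The "main-chain" report metric superposes on all 10
heavy atoms and reports RMSD over {N, CA, C, O1, O2}. Note that this
metric saturates around 0.7 Å for pure torsion changes (the five-atom
unit is internally rigid up to θ), so synthetic-mode recovery uses the
all-heavy-atom metric.

## Ensemble statistics and clustering

Descriptive statistics use the sample SD (n − 1; the ensembles are
small, n = 22) and VC% = 100·SD/mean. Torsions are circular: circular
mean and circular SD are reported and VC is flagged not applicable.

Clustering is agglomerative (scipy, single linkage by default, complete
available) cut at a threshold τ; cluster indices are ordered by
decreasing size, centers are medoids (minimum mean RMSD to co-members,
ties by lexicographic id), and intra-cluster RMSD is the mean over all
members' distance to the medoid (a two-member cluster at distance d has
intra d/2). Single linkage makes the partition a coarsening in τ.
Multiple alignment iterates superposition onto the evolving coordinate
mean, starting from the first conformer, until the mean moves < 1e-6 Å
(≤ 100 iterations; non-convergence is flagged, not raised).

## Synthetic ensembles

The generator perturbs the template in internal-coordinate space —
never Cartesian — so every sample is a chemically valid L-glutamate:
bonds and angles are drawn per-variable from Gaussians with the
dispersions measured across the deposited bound ensemble, torsions from
a mixture of modes (default: one extended mode (180,180,180,180) and two
folded variants (60,0,0,180) and (180,0,60,0), composition 16/3/3,
within-mode SD 8°). Samples with invalid geometry (angle outside
(0,180), steric clash < 0.5 Å, broken chirality) are redrawn, with a cap
of 1000 rejections. Conformers are rebuilt by NeRF and optionally
scattered by uniform random rotations and N(0, 5 Å) translations.

The default mode centers were chosen by a clash-free geometry search so
the nearest inter-mode all-heavy-atom RMSD (≥ 1.2 Å) exceeds the
within-mode spread (~0.2 Å mean pairwise) five-fold; any single-linkage
cut between the two scales — 0.7 Å is used throughout — recovers the
modes exactly. The generator does not emulate crystallographic error
models (B-factors, resolution effects, lattice contacts), so recovery
tests validate the statistics and clustering machinery, not
crystallographic noise behaviour.

## Vacuum energy model

The quantum-chemical ranking of vacuum conformers is out of scope; the
package uses a deliberately transparent fixed-parameter molecular
mechanics energy

E = Σ k_b (r − r₀)² + Σ k_a (θ − θ₀)²
  + Σ_{≥3 bonds} [ 4ε_ij((σ_ij/r)¹² − (σ_ij/r)⁶) + 332.0637 q_i q_j/(D r) ]

with Lorentz–Berthelot combining, 1-4 pairs scaled by 0.5, vacuum
dielectric D = 1. Equilibrium bond lengths r₀ are the averages over the
relaxed vacuum conformer database, equilibrium angles θ₀ the averages
over the bound ensemble; k_b = 300 kcal mol⁻¹ Å⁻², k_a = 0.02
kcal mol⁻¹ deg⁻² (≈ 65 per rad²) and the element LJ parameters
(C: 3.40 Å/0.086, N: 3.25/0.17, O: 2.96/0.21 kcal/mol) are
standard-order-of-magnitude force-field constants. The default species
is the vacuum anion — both carboxylates deprotonated, ammonium
protonated, net −1, charges collapsed onto heavy atoms (N +1; each
COO⁻ as C +0.70, O −0.85×2) — with a neutral-side-chain variant
available. Pairs closer than 0.1 Å are clamped with a warning rather
than returning infinities. Only the relative ordering of conformer
energies is meaningful; absolute values depend on the charge collapse
and are not comparable to quantum-chemical total energies.

## Torsion scan and conformer database

The scan enumerates a regular grid (default 30° over 4 torsions:
12⁴ = 20 736 points, each axis −180, −150, …, 150) with bonds and angles
frozen at the template, so the bonded energy is constant and torsional
preferences come entirely from the nonbonded terms. Every grid point is
locally minimised over the scanned torsions (L-BFGS-B, gradient
tolerance 1e-6 kcal/mol; descent from the start is guaranteed, a start
that is already stationary is returned unchanged). Endpoints are
collapsed at 0.05° resolution (they are the same stationary point),
then deduplicated greedily in ascending energy at 0.1 Å symmetric
all-heavy-atom RMSD — kept conformers are therefore pairwise > 0.1 Å
apart and the lowest-energy representative of each basin survives; the
pass is idempotent. The retained set is ranked by energy, grouped by
single linkage at 0.5 Å (group 1 contains the global minimum), and
annotated: *rounded* iff min(N···OE1, N···OE2) < 4 Å, else *extended*;
ammonium hydrogens are placed geometrically (N-H 1.01 Å, tetrahedral,
staggered against the CA substituents) purely for H-bond reporting
(criteria: H···O ≤ 2.5 Å and N-H···O ≥ 120°) and never enter RMSD or
bonded energy terms.

With the default parameters the global minimum is a rounded conformer
with an internal N-H···OE hydrogen bond, far below the best extended
conformer — the qualitative vacuum-versus-bound contrast the package is
built to demonstrate. The sizes of the unique-conformer set and of the
similarity grouping depend on the surrogate energy surface and are
reported as computed, not calibrated to any external count.

## Problem sizes and determinism

Default problem sizes: 22-member synthetic ensembles for clustering
(matching the bound ensemble), n = 200 for statistics recovery, the full
20 736-point grid for the vacuum scan (~4 minutes on one core; the fast
scalar NeRF + pair loop evaluates one energy in ~20 µs). Everything is
deterministic given the configuration; the only randomness is the
synthetic generator's seed. Grid enumeration order is lexicographic;
dedup ties break by energy then torsion vector; medoid ties by id.

## Known limitations

- The surrogate energy cannot reproduce quantum-chemical conformer
  counts, absolute energies or fine H-bond geometry; only the
  qualitative rounded-below-extended ordering is asserted.
- Hydrogen placement is idealised (no pyramidal inversion, no torsional
  relaxation of the ammonium group).
- PDB parsing handles single-conformer alternate locations by highest
  occupancy (ties → 'A'); residues missing any heavy atom are skipped,
  never rebuilt.
- The main-chain report metric is one of several possible readings of
  "main-chain RMSD" for a free amino acid; the all-heavy-atom metric is
  provided alongside.
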