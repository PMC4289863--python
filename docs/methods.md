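# Methods

This note documents the models, numerical choices and known limitations
behind ectofit's four computational blocks: simulated-density synthesis and
scoring, restrained flexible fitting, rigid-body Monte Carlo docking and
screening, and center-of-mass hinge metrics — plus the synthetic generator
that provides ground truth for all of them.

## Simulated density maps

A map is synthesized by placing an isotropic Gaussian at every heavy atom,
amplitude proportional to atomic mass, with σ = R/(2√(2 ln 2)) so the kernel
FWHM equals the nominal resolution R (default 4 Å on a 1 Å grid; the kernel
convention is recorded in the map metadata so σ = R/2 or similar variants
can be compared). Kernels are truncated at 4σ: a 3-D Gaussian keeps 99.89%
of its mass inside 4σ, so the voxel sum of a map matches Σ mᵢ·(2πσ²)^{3/2}/h³
to ~0.1%; at 3σ the loss would already be 2.9%. Grids are aligned to the
spacing lattice, which makes integer-voxel translations exact. Maps are
written/read as MRC/CCP4 mode-2 via gemmi, with the nominal resolution kept
in a spare header word and axis-order permutations normalized on read.

The cross-correlation coefficient (CCC) between a model and a target map is
the Pearson correlation computed over voxels where the target exceeds a
threshold (default 1% of the target maximum), after synthesizing the model's
map on the target's grid at the target's resolution. The above-threshold
masking convention matters for absolute CCC values and is therefore stated
wherever a CCC is reported. By the Pearson property the score is invariant
to affine rescaling of map values.

## Map potential and internal restraints

Fitting minimizes E_map + E_internal. The map term is per-atom:
E_map = ξ Σ wᵢ (1 − ρ̂(rᵢ)) with ρ̂ the map clamped below the threshold and
normalized to [0, 1] by the map maximum, wᵢ = mᵢ/⟨m⟩ over the fitted atoms,
and ξ = 0.3 kcal mol⁻¹ per unit normalized density by default (a per-stage
config value; doubling ξ exactly doubles map energies and forces). Values
and gradients come from trilinear interpolation with the analytic gradient
of the interpolant; atoms in sub-threshold regions sit on a flat plateau
(zero map force), and atoms outside the grid are clamped with zero gradient
and flagged.

In a multi-component stage each map can be scoped to the selection it
describes — the usual multi-map convention. This is not cosmetic: a small
component placed beside a large one lies inside the neighbour's Gaussian
skirt, and an unscoped potential exerts a steady pull toward the neighbour's
density that the soft repulsion only partially balances.

The internal model replaces a molecular-mechanics force field with harmonic
terms referenced to the starting geometry (energy convention k·Δ², no ½):

- bonds detected by distance (< 1.9 Å heavy-heavy, S–S to 2.3 Å),
  k = 200 kcal mol⁻¹ Å⁻²; angles from the bond graph, k = 50 kcal mol⁻¹ rad⁻²;
- peptide ω torsions restrained to 180° (k = 100), keeping peptide bonds
  trans;
- one improper torsion (N, C, CA, CB) per residue restrained to its start
  value (k = 100); a mirror flip reverses its sign, so Cα chirality cannot
  invert silently;
- φ/ψ restraints with k = 300 kcal mol⁻¹ rad⁻² on residues inside detected
  secondary-structure elements. The default detector marks residues i..i+4
  helical when the backbone O(i)–N(i+4) distance is ≤ 3.5 Å within a
  covalently continuous segment (no hydrogens needed); a φ/ψ-window detector
  (helix φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); strand φ ∈ (−180°, −90°),
  ψ ∈ (90°, 180°)) is available. Chain breaks (C–N > 2 Å) terminate
  segments. Loops stay unrestrained;
- a Cα elastic network (k = 2 kcal mol⁻¹ Å⁻², cutoff 9 Å, intra-chain
  pairs only) that preserves each chain's tertiary packing, standing in for
  the attractive nonbonded terms of a force field. Without it a misoriented
  component shears internally to fill density instead of reorienting
  rigidly; restricted to intra-chain pairs it cannot freeze the relative
  placement of components, which is exactly what a fit must change. The
  network also never bridges domains placed further apart than the cutoff,
  so interdomain hinge motions stay free;
- soft-sphere repulsion k·(r₀ − r)² between non-bonded heavy atoms (pairs
  within three bonds excluded), with per-element radii chosen small enough
  (C 1.35 Å, N 1.25 Å, O 1.2 Å) that native packing is essentially
  penalty-free;
- optional positional tethers (k = 10 kcal mol⁻¹ Å⁻²) implementing a
  stage's "positionally restrained" set.

All torsion gradients are analytic and verified against central finite
differences in the test suite.

## Minimization and the staged protocol

Each stage runs a limited-memory quasi-Newton descent (L-BFGS two-loop,
memory 12) with Armijo backtracking and a hard cap (default 0.2 Å) on the
per-step atomic displacement. The quasi-Newton choice is load-bearing: the
energy mixes very stiff terms (k ≈ 200–300) with very soft ones (map forces
of order 0.1 kcal mol⁻¹ Å⁻¹), and plain steepest descent advances the soft
collective modes — a rigid slide of a whole component into its density — by
~10⁻³ Å per step once the stiff modes set the stable step size. Curvature
pairs recover those modes; the displaced-helix test regains 3 Å in under a
thousand iterations. The logged energy is monotone non-increasing by
construction; a stage aborts on non-finite energy or after ten consecutive
failed line searches (unless the achievable decrease is below the
convergence tolerance, which means a minimum was reached). Convergence is
declared when the energy decrease over a 50-step window falls below
10⁻⁴ kcal mol⁻¹ per step.

A protocol is a list of stages, each naming the mobile selection, the
positionally restrained selection, the active (possibly scoped) maps and the
step budget; stages run in order from the previous stage's coordinates, and
the concatenated trajectory carries stage markers, per-frame energies, CCC
against the combined target and a direct (unsuperposed) Cα-RMSD trace
against a reference when one is given (a superposed variant is available
and the convention is recorded in the trace output).

Two optional devices handle starts beyond the reach of local descent, both
deterministic given the run seed and both off by default (the shipped
benchmark does not need them): per-stage multi-start (rigid rotation +
translation jitter of each mobile chain, lowest final energy kept) and a
rigid pre-dock (a short Metropolis search per mobile chain, scored by
1 − CCC plus clash, before relaxation).

## Rigid docking and screening

`mc_dock` runs a Metropolis chain over rigid poses of one component:
proposals compose a rotation about a uniform random axis (angle uniform up
to 10° by default) with a translation uniform in a ball (2 Å default);
acceptance is exp(−ΔE/T) at T = 1 reduced unit by default. The energy is
w_clash·E_clash + w_map·E_map, with E_clash the soft-sphere penalty over
heavy-atom pairs closer than 2.5 Å and E_map either the mean per-atom map
potential (cheap; default) or 1 − CCC against the summed map (a shape match,
much more orientation-sensitive — preferred when the pose's rotation must be
resolved). Runs are bitwise reproducible from the seed; results carry every
accepted pose, the acceptance rate and the best (lowest-energy) pose.

Screening evaluates candidate conformations against the density reserved
for other components: the overlap score is the fraction of heavy atoms in
voxels above the threshold (atoms outside the grid count as
non-overlapping), optionally plus a clash count against fixed atoms. A
candidate passes when overlap ≤ tolerance and clashes ≤ tolerance (both zero
by default, the "no overlap" criterion); records are sorted by overlap then
clash count, and loosening tolerances can only grow the passing set.
`select_low_energy` ranks equal-composition fragments by clash energy
against a fixed context (plus an optional map term) with stable tie-breaks.

## Hinge metrics

Domain centers of mass are mass-weighted means over heavy atoms (hydrogens
excluded by default). Hinge "X-Y" is the angle at a junction domain's COM
subtended by two flanking COMs; the triplet mapping is configuration data
because published values depend on it. The shipped convention for the
receptor leg L1-CR-L2-F1-F2-F3 is: L1-L2 at CR between L1 and L2; L2-F1 at
L2 between CR and F1; F1-F2 at F1 between L2 and F2; F2-F3 at F2 between F1
and F3 — and every report prints its convention. Deltas against a reference
are signed model − reference (negative = contraction); asymmetry is the
absolute cross-subunit difference. Angles are invariant under rigid motion,
uniform scaling about the vertex, and mirror reflection. Superposition uses
the closed-form least-squares rotation (SVD with sign correction, so
reflections are never returned); degenerate (collinear or < 3 point) inputs
raise. Residue-residue contacts report the minimum heavy-atom distance per
residue pair up to a closed 5 Å cutoff by default (the "vicinity" radius).

## Synthetic generator

The generator provides every test's ground truth in closed form.

- **Toy receptor.** Each domain is a three-helix poly-ALA bundle (ideal
  geometry built by torsion-space chain extension: φ = −57°, ψ = −47°,
  ω = 180°); domain COMs are placed on a planar polyline whose interior
  angles are the designed hinge angles (default 120°, 150°, 90°, 80° on six
  domains named L1, CR, L2, F1, F2, F3), with each bundle translated so its
  heavy-atom COM lands exactly on its vertex — hence hinge recovery to
  numerical precision before any optimization. The dimer's second subunit
  is a proper two-fold rotation of the first (a reflection would invert
  chirality), giving zero hinge asymmetry by construction. Layouts whose
  COMs self-intersect are rejected.
- **Deformations.** A hinge delta rotates all domains downstream of the
  hinge vertex rigidly about the vertex COM in the plane of the two arms;
  downstream geometry moves as one rigid body, so all other hinge angles
  are provably untouched. One-sided deformations produce the designed
  asymmetry exactly. Deformations that clash or leave (0°, 180°) are
  rejected.
- **Fitting benchmark.** Three components — a 3-helix bundle with helix
  lengths 12/10/8 ("L1"), a two-helix 12/8 bundle ("hormone") and a kinked
  8+5-residue helix ("alphaCT") — are placed contact-free; target maps at
  4 Å / 1 Å are synthesized per component on a shared grid plus their sum.
  The start displaces the components rigidly (2.0 / 7.5 / 5.5 Å with 5° /
  20° / 12° rotations; directions seed-dependent, the smaller components
  displaced tangentially to the large one — a misplaced-but-metastable
  start that must slide along the neighbour's surface), giving a start
  Cα-RMSD of ≈ 5.3 Å, the scale of a substantial multi-component
  misplacement. Unequal helix lengths and the kink are deliberate: an
  idealized poly-ALA helix blurred to 4 Å is a nearly featureless cylinder
  whose axial register and rotation are genuinely unidentifiable from
  density (real peptides carry sidechain features), and equal-length
  two-helix bundles have a flip pseudo-symmetry.
- **Docking toy and screening ensemble.** A two-helix ligand is planted
  clash-free beside a receptor bundle; its map is synthesized at the
  planted pose and the start is offset 3 Å / 20°. Screening decoys are
  receptor copies pushed into the ligand's density region.

What the generator does **not** emulate: real sequences and sidechains,
experimental map noise, B-factor heterogeneity, solvent contributions,
symmetry constraints, or flexible linkers between domains (toy domains are
spatially separated segments of one chain). Passing the synthetic
benchmarks therefore demonstrates the correctness and convergence of the
machinery under idealized, noise-free maps with exactly known answers — not
performance on experimental data.

## Reproducibility and problem sizes

All stochastic components (move proposals, restart jitter, benchmark
displacement directions) draw from a single seeded generator per run, and
generator outputs are bit-reproducible from their spec and seed. The shipped
problem sizes — ~300-atom components, map grids of ~60³ voxels, 2,000-step
stages, 20-seed docking repeats, 50-member screening ensembles — keep a full
end-to-end run (the acceptance script) around half a minute on one CPU while
leaving every recovery criterion comfortably non-trivial.

## Known limitations

- The internal model is not a force field: energies are not thermodynamic,
  and fitted models should be re-minimized with a proper force field for
  downstream use.
- The density potential is local; a start misplaced by much more than the
  kernel support (4σ beyond the component's own envelope) feels no pull,
  and a badly misoriented start can converge into density in a wrong
  orientation — the standard caveat of density-guided fitting. The CCC-based
  pre-dock mitigates but does not eliminate this.
- CCC values depend on the masking convention; compare only like with like.
- Published hinge angles for real receptors depend on domain boundaries and
  triplet conventions from the original analyses; the shipped config may
  need calibration against those to reproduce printed values.
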