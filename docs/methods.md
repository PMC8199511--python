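# Methods

## Overview

`elfx` predicts how two closed-shell molecules prefer to approach each
other by (1) locating each molecule's nucleophilic and electrophilic
domains as attraction basins of a frontier-weighted electron
localization function, (2) condensing the frontier (Fukui) densities
over those basins into point monopoles, and (3) scanning rigid-body
arrangements of the pair under a monopole Coulomb score, `E_dual`.
The flagship application is the guanine–cytosine base pair, where the
favourable approach should reproduce the Watson–Crick arrangement.

## Localization fields

For an N-electron single-determinant wavefunction the ELF kernel is

    chi(r) = [tau(r) - |grad rho|^2 / (8 rho)] / (c_F rho^{5/3}),
    c_F = (3/10)(3 pi^2)^{2/3},

with `tau = 1/2 sum_i n_i |grad phi_i|^2` the positive-definite
kinetic-energy density, and `ELF = 1/(1 + chi^2)`.  The
frontier-weighted variant divides the kernel by twice the frontier
weight `x(r)`:

    ELF_x = 1 / (1 + (chi / 2x)^2),
    x = rho_HOMO / rho_N            (nucleophilic side)
    x = rho_LUMO / rho_{N+1}        (electrophilic side)

On the electrophilic side the kernel itself is built from the N+1
system's density and kinetic-energy density (ground-state orbitals with
the LUMO additionally populated, frozen geometry).  Frontier densities
are unit-normalized (one electron per Fukui function) by default; an
occupation-weighted convention (integral 2) is available for
sensitivity checks.  Degenerate frontier orbitals (within 1e-5 hartree)
are averaged with equal weights so the fields cannot depend on
arbitrary orbital ordering.

Numerical conventions: points with `rho < 1e-12 e/bohr^3` are vacuum
and all fields are defined as 0 there (not 1), which prevents spurious
far-field attractors; the Pauli term is clamped to 0 when round-off
drives it into [-1e-10, 0); nodes with `x < 1e-10` get `ELF_x = 0`.

## Wavefunctions

Wavefunctions come from Molden or AIM wfx files, or from the built-in
restricted Hartree–Fock backend (McMurchie–Davidson Gaussian integrals,
numba-compiled, DIIS-accelerated SCF; closed-shell singlets only).  The
backend exists so every fixture molecule can be treated offline; it was
validated against textbook minimal-basis H2 values, scipy-based
quadrature oracles for each integral class, and variational convergence
to the known Hartree–Fock limits of He and Ne.  An external engine
(pyscf), when installed, can be used for other methods; it is optional
and absent by default.

### Desk-scale level of theory: HF / "sto-3g+"

Production-level analyses of this kind use hybrid DFT with large
diffuse basis sets.  At desk scale we use the classic STO-3G
parametrisation augmented with one even-tempered diffuse sp shell on
each non-hydrogen atom, with exponent `alpha_min(2sp)/3.1` (the fit's
own geometric progression continued one step).  The diffuse
augmentation is not cosmetic: the LUMO of a planar pi system in any
valence-only basis is a pi* orbital with a strict nodal plane, so the
electrophilic frontier density vanishes identically in the molecular
plane and no electrophilic domains can form around the in-plane N-H
hydrogens — yet those domains are precisely what drives hydrogen-bond
donor recognition.  With the diffuse shell the virtual space acquires
sigma-capable outer functions and the electrophilic ELF_x domains
concentrate in caps around the hydrogens, the qualitative structure
reported by production-level diffuse-basis analyses.  A softer exponent
(progression ratio 4) was found to merge those caps into a single
outer-envelope basin and was rejected on that qualitative ground.

## Basin partition and condensation

Fields are sampled on axis-aligned grids (default 0.2 bohr spacing,
5 bohr margin; 0.25 bohr for the acceptance-scale base-pair runs).
Every non-vacuum node is assigned by discrete steepest ascent over the
26-neighbor graph: each node points to the neighbor with the largest
positive value gain per unit distance, ties resolved to the lowest flat
index; on exact plateaus a node points to the lowest-indexed
equal-valued neighbor only if that index is below its own (plateau
chains strictly decrease, so no cycles).  Attractors closer than
0.4 bohr are merged (grid noise splits symmetric maxima).  The matching
Fukui density is condensed over each basin's nodes by exact nodewise
bookkeeping.

Two corrections keep the monopole model faithful to the Fukui sum rule:

- **Sum-rule restoration** (default on): a finite grid box truncates a
  few percent of a diffuse acceptor density.  Basin populations are
  rescaled so each side sums exactly to the Fukui charge *before*
  pruning.  Without this, the dual energy acquires a spurious
  net-monopole term proportional to (total nuclear charge) x
  (population imbalance), large enough to bury the orientation signal.
- Pruning: basins whose attractor sits within 0.35 bohr of a nucleus
  with Z > 2 are core basins and are dropped; populations below 0.01 e
  are dropped.  Pruned charge is *not* redistributed.

## The dual interaction energy

For two site models A and B the monopole score is

    E_dual = sum_{a,b} [ 2 N_Nu^a N_Nu^b - N_Nu^a N_El^b
                         - N_El^a N_Nu^b ] / r_ab
           + sum_{A atoms, b} q_A (N_El^b - N_Nu^b) / r
           + sum_{B atoms, a} q_B (N_El^a - N_Nu^a) / r

(populations in electrons, distances in bohr, energies in hartree;
there is deliberately no El-El term and the Nu-Nu repulsion carries a
factor 2).  Nuclear couplings are summed once per (atom, site) pair;
a literal mode that nests them inside the double basin sum is kept for
comparison.

### Frame charges q_A

The atomic monopoles `q_A` of the molecular frame are, by default, the
*screened* net atomic charges rather than bare nuclear charges.  In the
underlying interacting-quantum-atoms energy the nuclear deltas always
appear as `Z_A delta(r - R_A) - rho(r)` — nuclei screened by the full
electron density — and at monopole order that difference is the net
atomic partial charge.  Read with bare Z (total 78 for guanine) the
nuclear couplings outweigh every Fukui site-site term by more than an
order of magnitude and the orientation map degenerates into "approach
the densest donor face", which contradicts the method's own reference
results.  Screened charges are computed by radius-scaled Voronoi
condensation of the ground-state density on the analysis grid (each
node belongs to the atom minimizing d_A/r_A with Bragg–Slater radii;
plain Voronoi cells over-assign bond density to hydrogen and invert its
charge, and Mulliken projection is unusable with diffuse functions).
`frame_charge_screening="none"` restores the bare-Z reading.

A brute-force two-grid quadrature of the underlying Fukui-function
Coulomb integral serves as the oracle for the monopole truncation: it
reproduces `E_dual` exactly for point-collapsed distributions and
converges to it as separation grows.

## Orientation scan

The fixed molecule sits in its principal-axes frame (z = largest
moment of inertia, i.e. the out-of-plane normal for planar molecules;
x = smallest; signs fixed by third mass moments).  The mobile
molecule's centre of mass is placed on a sphere of radius d (default
8 A) at each (theta, phi) on a 10-degree grid; its orientation is
optimized at each cell by a deterministic coarse search over 576 unit
quaternions (fixed-seed uniform stream; sets for different sizes are
prefix-nested so refining the coarse grid can never raise a cell)
followed by Nelder–Mead refinement on a rotation-vector perturbation
(tolerance 1e-8 hartree).  Orientations bringing any intermolecular
atom pair closer than 1.5 A are rejected — the monopole score has no
repulsive wall.  Everything is grid-based or seeded: identical inputs
give bit-identical maps.

Stationary points are local minima on the sphere topology (periodic
azimuth, pole rows treated as single points), deduplicated within 15
degrees of arc.  For structure export the separation, sphere angles and
orientation are relaxed jointly (rigid monomers, penalized clash), then
hydrogen bonds are counted with a geometric criterion: donor N/O with
bound H, acceptor N/O of the partner, D...A <= 3.5 A, H...A <= 2.5 A,
D-H...A >= 120 deg.  The H...A condition is required: a heavy-atom
cutoff alone counts bifurcated secondary contacts (H...A 2.6-2.7 A)
that no structural assignment would call hydrogen bonds.

## Fixtures

Analytic toy wavefunctions (normalized s-Gaussian orbitals with
closed-form rho, grad rho, tau) anchor the generic evaluator; a single
doubly-occupied orbital satisfies tau = |grad rho|^2/(8 rho) exactly
and has ELF = ELF_x = 1 everywhere, which exercises the whole field
stack against exact values.  Monomer geometries are idealized:
textbook experimental parameters for water/ammonia/formaldehyde, and
MMFF94-optimized planar canonical tautomers for the nucleobases.  The
reference Watson–Crick pair is a rigid in-plane fit of cytosine onto
guanine's WC edge at canonical heavy-atom distances (N4...O6 2.91 A,
N3...N1 2.95 A, O2...N2 2.86 A); nothing downstream depends on these
coordinates beyond the hydrogen-bond-pattern level.  Seeded generators
provide random site models (for the Eq.-oracle tests) and planted
two-well maps (for stationary-point recovery).

## What the desk-scale run does and does not show

At HF/sto-3g+ with 0.25 bohr grids and a 10-degree map, the
guanine(fixed)–cytosine(mobile) scan at 8 A concentrates its attractive
basin on the Watson–Crick face of guanine (the deepest map cells sit
within 30–40 degrees of the reference WC direction), the rigid
refinement of the global minimum relaxes the centre-of-mass separation
to ~5.9 A (the reference value is close to 6 A), and the neighbouring
stationary points refine into structures held by one to three
N-H...N/O hydrogen bonds.  The *specific* Watson–Crick triple
(O6...H-N4 / N1-H...N3 / N2-H...O2) is not the global minimum's refined
structure at this level: the HF/sto-3g+ frontier orbitals put their
largest nucleophilic lobes on ring-carbon pi positions rather than on
the O6/N3 lone-pair regions that dominate at the production level, and
the amino-amino bridged arrangement scores slightly better.  This is a
limitation of the reduced level of theory, not of the pipeline
machinery; the machinery itself is validated by the exact and oracle
tests described above.

## Problem sizes

Default test and acceptance runs use: guanine 88 basis functions /
~314k grid nodes, cytosine 61 / ~252k, 19 x 37 map cells x 576
orientations.  The full base-pair pipeline takes roughly 7-8 minutes on
one CPU, dominated by the two-electron integrals and the grid
evaluation of the fields.
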