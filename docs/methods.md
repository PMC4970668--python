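# Methods

## Coarse-graining

A protein residue is represented by one bead at its Cα position. The bead
mass is the sum of the atomic masses of the residue's atoms *as present in
the input file*: crystal structures routinely miss atoms, and using only
what the file contains keeps the model reproducible from its input alone. A
flag switches to full chemical-component masses from the internal table for
users who prefer idealized masses; the two options differ by at most a few
Daltons per residue and have no qualitative effect on mode shapes.

Bound guanine nucleotides are reduced to moiety beads at the mass-weighted
centroid of each group: guanine base, ribose, and one bead per phosphate.
The γ-phosphate group of GTP is defined as PG, O1G, O2G, O3G plus the β–γ
bridging oxygen O3B, so that GDP is exactly the GTP partition minus those
five atoms. In GDP component files the name O3B denotes a terminal
β-phosphate oxygen (the bridge remains with β after hydrolysis), so moiety
assignment is nucleotide-kind-aware. Moiety beads are chained
base–ribose–Pα–Pβ(–Pγ) with covalent-class springs and coupled to protein
beads through the same hydrogen-bond/van der Waals rules as protein pairs.

Alternate locations are resolved by keeping the highest-occupancy altloc
(alphabetic first on ties). Coordinates are Å throughout; residue numbers
stay 1-based as in the source file; bead indices are 0-based.

## Interaction classification and spring constants

Residue pairs are classified with coordinate-only criteria:

| class | rule | default k |
|---|---|---|
| backbone | consecutive residue numbers in one chain | 100 |
| ionic | Asp/Glu vs Lys/Arg/His charged-group atoms ≤ 4.5 Å | 20 |
| hydrogen | backbone N···O ≤ 3.5 Å (no angle term at Cα resolution) | 10 |
| vdW | remaining Cα pairs ≤ 8 Å | 1 |
| nucleotide covalent | adjacent moiety beads | 100 |

One edge per pair, priority backbone > ionic > hydrogen > vdW. Spring
constants are model units, not calibrated to an absolute energy scale; every
downstream comparison is a ratio, rank or correlation, so only the ratios
matter. The defaults above are this package's stated convention and are
fully configurable through a YAML table. Setting all classes equal recovers
a traditional distance-cutoff network. The 8 Å classification cutoff and
the 12 Å pathway-interpolation cutoff are deliberately independent knobs.

Binding partners (a receptor, a Gβγ subunit) are added as *immobile
anchors*: their beads join the network, edges to them are classified by the
same rules, but their degrees of freedom are eliminated, so the eigenproblem
stays the size of the bare model. With atomic records absent (bead-only
synthetic models) anchor edges fall back to Cα-distance vdW classification.

## Normal mode analysis

The generalized problem K u = λ M u is solved by dense symmetric
diagonalization of M^{-1/2} K M^{-1/2} (LAPACK `eigh`); systems beyond 500
beads with a requested mode count use a sparse shift-invert solver instead,
and the two agree to 1e-6 on overlap quantities. Eigenvalues below
1e-8 × λ_max are treated as zero modes — a free connected network has
exactly six. Eigenvector signs are fixed (largest-magnitude component
positive) so outputs are bit-reproducible. Mean squared fluctuation is

MSF_i = Σ_m (1/λ_m) |φ_m(i)|², φ = M^{-1/2} u,

summed over non-zero modes, with k_BT ≡ 1: all reported mobility
comparisons are percentile- or ratio-based, so the absolute scale cancels.
Reports index modes from the first mode of the solved system including zero
modes and also give the elastic-only index, since "fourth mode" conventions
are ambiguous across the literature.

Two independent oracles back the MSF implementation in the tests: the dense
pseudo-inverse of the mass-weighted Hessian (agreement to 1e-8), and direct
Boltzmann Monte-Carlo sampling of exp(−δᵀKδ/2) on small anchored systems
(agreement within 5 % at 2×10⁵ samples).

## Pathway interpolation

Intermediates minimize the distance-matching cost C(δ) over the union
contact map (12 Å in either endpoint), with target lengths linearly
interpolated at α_k = k/steps (default 50 steps; the cost landscape is
smooth on the systems studied and 20 steps already converge). The solver is
damped Gauss–Newton: the linearized pair-distance residuals form a sparse
Jacobian, each update is the minimal-norm LSMR solution (which also handles
the rigid-motion degeneracy of the cost), and a halving line search accepts
only non-increasing cost. Convergence is declared when the largest per-bead
step falls below 1e-6 Å or after 100 iterations. Because the cost is
invariant under rigid motion, each accepted intermediate is superposed onto
its predecessor to remove drift — a convention, not physics.

Reported per step: α, the residual cost at the solution, and superposed
RMSD to the start conformation. For endpoints related by pure rigid motion
every interpolated target is exactly embeddable and all costs vanish; for
genuinely deforming transitions the interior costs are positive and peak
mid-path, while both endpoint costs are (numerically) zero — interpolated
distance matrices are generally not embeddable in 3-D, which is the
geometric reading of intermediate states being strained relative to the
endpoints. The maximum residual over a *finer* α grid can slightly exceed a
coarser grid's maximum because new α values (near the least-embeddable
point) are sampled; at shared α values refinement never increases the
residual.

## Overlap validation

Overlap uses Cartesian mode shapes exactly as defined above. On
mass-weighted systems the non-rigid Cartesian shapes are not orthonormal,
so the completeness identity ΣO² = 1 is guaranteed only in uniform-mass
coordinates; the completeness test therefore uses uniform masses. "First
5 % lowest modes" means ⌈0.05·3N⌉ *elastic* modes — zero modes are excluded
since a rigid motion carries no information about an internal change and is
removed from Δr by the superposition anyway.

## Mobility comparison

A mobility change between two states is the difference of within-profile
percentile ranks (average fractional rank × 100, scipy `rankdata`), giving
values in [−100, 100] that are antisymmetric under swapping the states and
invariant to monotone rescaling of either profile. Note that when the
residue pairing covers all residues the *mean* percentile change is
identically ~0 (both rank sums are equal); whole-model averages are
therefore reported as percent change of raw MSF, which is the quantity a
statement like "average decrement of 12.9 %" refers to.

An important subtlety governs anchored-vs-free comparisons. The free
system's MSF excludes rigid motions (pseudo-inverse), whereas anchoring
turns a rigid rotation into an elastic pivot about the anchor patch; for a
small patch that pivot is soft and can dominate, so anchoring a free model
may *raise* its mean MSF. Among anchored systems the comparison is clean:
adding constraints to a positive-definite system can only lower every
bead's fluctuation (Schur-complement inequality), which the tests verify
against the dense inverse. The binding-order experiment is accordingly
interpreted on anchored bases — which also matches the biological setting,
where every compared state carries a bound partner.

## Synthetic study systems

**Hinge pair** (defaults: 2 × 30-bead domains, 5 linker beads, 30°, 3.8 Å
spacing). Domains are face-centered-cubic bead blobs — rigid under the 8 Å
contact rule. The linker is a column of beads along the rotation axis (a
hinge pin) with a ±0.5 Å zigzag: geometry chosen so that counter-rotation
of the domains about the pin is the uniquely softest elastic motion, with
first-order restoring about two orders of magnitude above the zero-mode
tolerance and one below the next elastic mode. Extended or straight linkers
instead leave exact first-order mechanisms (free pseudo-dihedrals,
collinear springs), which is why naive hinge constructions fail. The open
conformer rotates domain B rigidly about the pin axis, so the generator's
angle is exact ground truth for the domain-rotation estimator (recovered to
≪0.1°). Seeded jitter ≤ 0.1 Å breaks lattice symmetry; it is applied before
the rotation so both conformers share it.

**Elastic chains.** The straight chain is three-dimensional with
nearest-neighbor springs; the diatomic case has the closed-form eigenvalue
k(1/m₁+1/m₂). The ring is built as a genuinely one-dimensional periodic
chain (one degree of freedom per bead, `dim=1` on the network) because only
then is the spectrum exactly the circulant closed form (4k/m)sin²(πj/n); a
3-D polygon with central-force springs has no such clean form.

**Pocket–ligand toy** (12 cage beads on an 8 Å sphere, 1 ligand bead).
Cage beads link to their six nearest neighbors — a triangulated, rigid
shell (a sparser shell has internal mechanisms) — with seeded heterogeneous
spring constants, giving a structured MSF profile; a symmetric cage has a
flat profile on which correlations are meaningless. The ligand couples to
every cage bead at a tunable attachment stiffness. Zero attachment drops
the edges entirely (protein dynamics exactly equals the empty cage); the
weak-coupling regime where the with/without-ligand MSF correlation exceeds
0.99 sits near attachment ≈ cage-stiffness/5, located by scanning. The
attachment → 0⁺ limit is singular: a nearly-free ligand contributes
near-zero modes whose 1/λ weight contaminates protein MSF, so "weak" does
not mean "arbitrarily small".

What these generators do *not* emulate: sequence-dependent contact
chemistry (ionic/hydrogen classes only exercise on atomic inputs),
secondary structure beyond the helix trace used in the torsion test, and
crystallographic artifacts (altlocs, missing atoms are covered by
hand-written atomic fixtures instead). Passing tests demonstrate the
mechanics of the pipeline and its numerical contracts, not the biological
accuracy of any particular stiffness table.

## Problem sizes and numerical choices

Default test and acceptance runs use 65-bead hinges (200 beads for the
pathway-convergence checks, 50 steps), ≤ 13-bead oracle systems, and
2×10⁵ Monte-Carlo samples; all complete in seconds on one CPU. Zero-mode
tolerance 1e-8 relative; Gauss–Newton step tolerance 1e-6 Å; eigenpair
residuals are verified at ≤ 1e-8 ‖K‖. Degenerate inputs (coincident bonded
beads, collinear superposition selections, constant B-factor series, zero
displacement vectors, empty regions) raise informative errors rather than
returning garbage.

## Known limitations

- Engineered (chimera) models are assembled by anchor superposition only;
  no energy refinement of the grafted joint is attempted, so grafted
  coordinates can clash sterically. This is a deliberate trade for a
  self-contained pipeline.
- Anchors are fully immobile; there is no intermediate "heavy partner"
  regime.
- The hydrogen-bond rule has no angular term — at Cα resolution an angle is
  not defined anyway.
- Harmonic fluctuations only: no time-domain dynamics, no anharmonicity, no
  solvent. ENI pathways are geometrically feasible interpolations, not
  minimum-free-energy paths.
- Percentile maps need ≥ 2 paired residues and are degenerate (all ties)
  on constant profiles.
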