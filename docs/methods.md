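# Methods

This note documents the models and procedures implemented in vesisphere,
the conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Reference sphere and great-circle geometry

All surface analyses reduce a frame to a reference sphere: the centre is
the equal-mass mean of the selected beads and the mean radius is their
average distance to that centre. Coarse-grained beads are treated as
equal-mass (bead masses are uniform in the CG representation the package
targets), so "weighted" centre-of-mass quantities reduce to arithmetic
means.

Great-circle distance between two beads is measured after radially
projecting both onto the reference sphere: d = R·angle(a−c, b−c), computed
via atan2 of |cross|/dot for stability near 0 and π. Beads sit at different
radii, so a projection convention is unavoidable; the frame's mean radius
is the only frame-level scalar available and is used throughout. Distances
"from the protein surface" are operationalised as the minimum great-circle
distance to any protein bead's radial projection; distance to the protein
COM is available by flag in the correlation profile (`distance_to="com"`).

## Spherical-harmonic shape decomposition

Per frame, bead radii r_i(θ_i, φ_i) are fitted with real orthonormal
spherical harmonics, l = 0..3, 16 coefficients. The real basis is built
from the complex scipy harmonics as √2·(−1)^m·Re/Im for m > 0 / m < 0
(Condon–Shortley-free), which keeps the basis orthonormal; orthonormality
is verified by Gauss–Legendre quadrature in the test suite to 1e−6.

Because the model is linear in the coefficients, the least-squares optimum
is found exactly by `numpy.linalg.lstsq` — a generic numerical minimiser
applied to the same objective converges to the same point, so the solver
choice is immaterial to the result. Rank deficiency (degenerate angular
coverage, e.g. coplanar beads) raises rather than returning an arbitrary
solution.

Conventions and caveats:

* **Normalisation.** With orthonormal harmonics, c₀₀/√(4π) equals the mean
  fitted radius and is exposed as `radius_equivalent`. All per-mode SD
  comparisons are internally consistent under any fixed convention.
* **Residual.** We report the RMS misfit per bead. When all lipid beads
  are fitted, the residual is dominated by the bilayer's radial structure
  (two leaflets at ±leaflet-offset around the mid-surface plus the
  head-to-tail bead spread), not by lack of shape flexibility — a
  single-valued surface cannot absorb a two-valued cloud. A headgroup-only
  selection (`selection="headgroup"`) gives a correspondingly thinner
  radial spread. Coefficient *fluctuations* are unaffected by this static
  offset.
* **Finite-sampling leakage.** With N fitted beads, the static radial
  spread σ_r leaks into fitted coefficients with SD ≈ σ_r·√(4π/N) as the
  bead configuration rearranges. At N ≈ 10³ this is ~0.1 nm — material
  against a 0.2 nm mode; at N ≈ 5×10³ it is ~2%. Closure tests therefore
  use ≥ 5×10³ beads.
* **l = 1 and centring.** An l = 1 radial deformation is, to first order,
  a rigid translation of the sphere. Re-estimating the centre each frame
  (the default, matching the fit-about-the-weighted-COM procedure)
  therefore absorbs part of any l = 1 mode into the centre estimate and
  mixes centre-estimation noise into the l = 1 series. Reported l = 1
  amplitudes are amplitudes *relative to the re-centred cloud*. Closure
  tests that inject l = 1 modes fit about the generator's fixed centre to
  separate coefficient statistics from the centring convention.

Mode statistics across a trajectory: per-mode SD (ddof = 1) and the
autocorrelation function with the biased (1/n) estimator normalised at lag
0, which keeps the implied spectrum non-negative. The ACF decay time is a
through-origin least-squares fit of log ACF(k) over the initial lags until
the ACF first drops below 0.05; constant modes are flagged, not silently
zero.

## Nearest-neighbour packing

MNND is exact: a k-d tree over lipid COMs, no cutoff truncation. MNNGC
projects COMs to the reference sphere and queries the tree on unit
vectors — the arc is monotone in the chord, so chord-nearest equals
arc-nearest and the result matches an O(N²) brute force exactly (asserted
in tests).

MNNGC is computed within each leaflet (per-lipid nearest-neighbour arcs
pooled over both leaflets). Projecting both leaflets onto one sphere would
let a lipid's trans-leaflet partner — at nearly the same angular
position — dominate the minimum and collapse the statistic below the
in-plane spacing; within-leaflet is the only convention under which the
great-circle statistic exceeds its chordal counterpart on a two-leaflet
vesicle, as observed in crowded-vesicle simulation studies. The naive
both-leaflet projection remains available (`per_leaflet_mnngc=False`).

Leaflet assignment: a lipid is in the outer leaflet iff its headgroup bead
is radially farther from the centre than its terminal tail bead (the tail
bead radially farthest from the headgroup). This tracks undulations,
unlike a fixed radius threshold.

## Radial distributions and the annular shell

Radial distributions use the signed coordinate r − R_mean (negative =
inner leaflet), default bin width 0.05 nm — fine enough to resolve
leaflet-spread SDs in the 0.3–0.4 nm range. The reported `sd` is the
pooled per-leaflet spread (each leaflet about its own mean); the raw SD of
the signed coordinate would be dominated by the bilayer half-thickness
itself. Peak-to-peak distance (outer peak − inner peak) is the bilayer
thickness proxy; one-sided distributions are flagged and peak-to-peak set
to NaN.

Annular classification: a lipid is annular iff its COM's great-circle
distance to the nearest protein bead projection is strictly below the
cutoff (default 2.0 nm), with a 1e−9 nm guard so boundary constructions
classify deterministically despite arccos rounding. Per-species annular
fractions are fractions of *all* lipids, so species fractions sum to the
total annular fraction. Residence times: a contact episode is a maximal
run of frames with min lipid-bead-to-protein-bead 3D distance below the
contact cutoff (default 0.6 nm, a first-shell CG bead contact); lifetime =
run length × dt. The default frame spacing convention throughout is 2 ns.

## Trimer interface classification and chains

Subunit contacts are cross-trimer subunit COM pairs within the cutoff
(3D, ≤; default 6.2 nm, configurable — 6.0 nm is a common alternative).
Classification by contact count: 1 → tip-to-tip; 2 sharing a subunit on
either side → tip-to-base; ≥ 3 → base-to-base. Two *disjoint* contacts
match none of the patterns; they are assigned the nearest pattern
(tip-to-base) with an `ambiguous` flag rather than silently binned.
Interfaces are recomputed independently per frame with no hysteresis; a
pair's first-contact time is the first frame it classifies.

Chains: a graph with trimers as nodes and classified interfaces as edges.
The longest simple path is exact by exhaustive DFS for components up to 12
nodes; larger components use a double-sweep BFS heuristic (exact on trees,
a lower bound otherwise) and the report is flagged `exact=False`.

## Protein-centred surface maps

Rigid-motion removal: per frame, a pure rotation about the vesicle centre
carries the protein COM direction onto its frame-0 direction, followed by
a spin about that direction aligning the protein's in-plane orientation.
The in-plane orientation is the first principal axis of the protein bead
cloud projected to the tangent plane, sign-fixed by the first bead; for a
transmembrane inclusion the principal axis is nearly radial, so when its
tangent projection is weak (< 0.25 of unit length) the tangential COM
offset of the first subunit is used instead — deterministic, three-fold-
symmetry-breaking, and noise-averaged. Pure rotations preserve radial
distances exactly; planted transport+spin is inverted to 1e−9 nm in tests.

The grid is an equiangular gnomonic (cube-face) projection centred on the
protein: grid lines at equal steps of great-circle distance along the two
edge directions (s = R·atan t), covering at most half a cube face (45°
half-angle). Cell assignment is binning in the two edge-arc coordinates.
Areal distortion of this projection is ≤ ~5% at 0.24 rad off-centre —
below Poisson counting noise at the sampling densities used (checked by
Monte Carlo). The grid's in-plane orientation is anchored to the protein's
own axis, making maps invariant under rigid global rotations of the input.

Height maps average, per cell, the per-frame mean radial distance of the
chosen leaflet's headgroup beads over the frames in which the cell is
occupied; cells never visited are NaN (missing), never zero. Thickness is
outer − inner cell-wise (missing propagates), so thickness + inner = outer
exactly. Occupancy maps count lipid-COM observations per cell and species
and report relative frequencies, which sum to 1 in every visited cell by
construction. Grid default 24×24 cells of 0.5 nm — between the lipid
nearest-neighbour spacing (~0.6–0.7 nm) and map smoothness.

## Direction correlations

A molecule's COM step from t to t+Δt defines the unit rotation axis
(r_t × r_{t+Δt})/|…| about the vesicle centre; reversing travel negates
the axis. Steps with numerically zero displacement have no axis and are
flagged NaN and excluded. cos θ between a lipid's and a protein's axes is
accumulated into the bin of the lipid's great-circle distance from that
same protein's surface at the step start (start-of-interval convention),
per lipid species, with per-bin counts so under-sampling at long Δt is
visible. Default bins: 0.25 nm out to 15 nm. Δt must be a multiple of the
frame spacing.

## The synthetic-trajectory generator

The generator is a statistical emulator, not a physics engine: no force
field, no thermostat, no Helfrich elasticity. Per step of length dt:

* **Lipids** take great-circle Brownian steps: isotropic tangent-plane
  Gaussian displacements with per-axis variance 2·D·dt (mean-square arc
  4·D·dt, verified against the closed-form 2D diffusion law to ~1%).
  Steps with RMS arc above 0.2 rad trigger a warning and sub-stepping.
  Lipids are rigid internally; COM radius, leaflet and species radial
  offset are preserved exactly.
* **Proteins** are rigid bodies rotated about the vesicle centre: two
  tangential rotation components (COM transport, variance 2·D_rot·dt
  each) plus a radial component (spin about the surface normal, variance
  2·D_spin·dt; defaults to D_rot). Transport and spin are independent
  dials because they play different roles — spin does not move the COM and
  therefore contributes no displacement axis.
* **Coupling**: lipids within r_c of the nearest protein surface move by
  the convex combination α·(protein rotation) + (1−α)·(own step). With
  `coupling_decay_length` λ set, the sharp shell is replaced by
  α(d) = α·exp(−d/λ) acting on every lipid. The expected direction
  correlation under equal per-axis step variances is
  g(α) = α/√(α² + (1−α)²); `recover_decay_length` inverts g on the pooled
  profile and fits log α against distance — the generator-aware closure
  estimator for λ.
* **Shape modes**: each selected (l, m) coefficient follows a stationary
  AR(1) process with prescribed SD and decay time (φ = exp(−dt/τ),
  initialised at stationarity); lipid radii are modulated by
  Σ c_lm(t)·Y_lm at the lipid's angular position, plus i.i.d. per-bead
  radial noise. AR(1) is the minimal stationary process with a tunable
  correlation time per mode, which is what distinguishes slowly-relaxing
  low-degree modes (microsecond-scale memory) from fast l = 2, 3
  fluctuations. Proteins receive no radial modulation, keeping them
  exactly rigid so that rigid-motion removal can be validated to machine
  precision.

`ground_truth` re-derives the exact realizations (coefficient series,
per-step coupling flags) from the seed; the generator is deterministic and
bit-reproducible for a fixed seed.

What passing closure tests show — and do not show. They show the analysis
chain recovers known structure of the kinds it claims to measure (injected
mode amplitudes and correlation times, planted shells, dimples,
enrichment rings, coupling ranges) at the stated tolerances. They do not
show that real CG-MD vesicles have this structure: the emulator has no
inter-lipid forces (positions are Poisson-like rather than
contact-packed, so absolute MNND/MNNGC values are larger than in packed
membranes), no protein aggregation dynamics (inclusions never attract),
no thermostat artefacts, and its undulations are imposed, not emergent.

## Builder

Per-leaflet lipid count is round(4πr²/APL) with r the leaflet's COM-sphere
radius (mid-plane radius ± leaflet offset, default 1.0 nm); default APL
0.64 nm² — a standard fluid-phase value for PC/PE-like CG lipids; the
analyses are insensitive to the default. Sites are a Fibonacci lattice
(quasi-uniform, deterministic); species are assigned by a seeded random
permutation matching the mix within rounding. Lipid bead geometry is a
straight chain (headgroup–linker–tails at 0.3 nm spacing, COM-centred),
oriented radially, heads outward on the outer leaflet and inward on the
inner. Proteins are placed at exact max–min arrangements for n ≤ 6
(antipodal pair, equatorial triangle, tetrahedron, bipyramid, octahedron)
and on a Fibonacci lattice beyond, each with a seeded random spin; any
lipid with a bead within the overlap cutoff (default 0.4 nm, one CG bead
diameter) of a protein bead is removed whole, and the removal count is
reported. No energy minimisation, solvation or counter-ions — those
belong to an MD engine.

## I/O and units

Internal units are nm and ns. mdtraj backs all coordinate I/O (GRO at
3-decimal nm precision, PDB with Å→nm conversion on read, XTC and
multi-frame GRO trajectories); residue names wider than three characters
are restored in written PDBs (the writer truncates them). Frame spacing is
inferred from stored times and must be uniform to 1%; multi-frame GRO
files are additionally scanned for bead-ordering changes between frames.
Since coordinate formats carry no role information, a small declarative
topology file maps (species, bead-name pattern) → role (headgroup, tail,
linker, protein backbone/sidechain, solvent), declares protein and solvent
species, and lists trimers as triples of molecule ids; shell-style
wildcards keep it compact. Solvent beads are skipped on read by default —
every analysis operates on lipid and protein beads. Results are written as
CSV at full float precision.

## Problem sizes in tests and the acceptance script

Surface fits use 5×10³ quasi-uniform points; mode-statistics closures use
2,000 frames of a 6 nm single-species vesicle at APL 0.64 (≈5,700 beads),
chosen so finite-sampling leakage (above) sits near 2%; packing and
aggregation oracles use 500 points and 100 random two-trimer
configurations; map closures use concentric shells of 2,500–4,000 lipids
per leaflet over up to 200 frames; correlation closures use 32.4 nm and
12 nm vesicles with thinned lipid densities (APL 0.7–6 nm²) giving ≥10⁴
samples per distance bin for the null. These sizes are the package's
validation conditions; the analyses themselves scale to full-density
multi-microsecond trajectories.

## Known limitations

* Leaflet assignment assumes lipids stay roughly radial; a lipid lying
  flat on the surface (rare in bilayers) could misclassify.
* The annular cutoff is measured to protein *beads*, not a smoothed
  molecular surface; with coarse beads the difference is below the bead
  radius.
* The longest-chain search is a lower bound above 12-node components.
* l = 1 mode amplitudes are convention-dependent (see centring note).
* The gnomonic grid accepts the projection's ≤5% areal distortion toward
  the corners rather than correcting for it; occupancy maps are relative
  frequencies per cell and are unaffected.
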