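# vesisphere

Analysis of coarse-grained lipid **vesicle** trajectories: global shape
dynamics by real spherical-harmonic decomposition, and local lipid/protein
organisation by great-circle geometry on the vesicle surface.

Planar-bilayer tools assume a flat reference plane and break down on a
30–65 nm vesicle, where every "lateral" quantity lives on a sphere.
vesisphere is for simulators of curved membranes — vesicles crowded with
trimeric membrane-protein inclusions (OmpF-like porins), mixed lipid
compositions (e.g. DSPC/DLPC, POPE/POPG) — who need the curved-surface
analogues of the standard bilayer analyses, plus a way to validate them
against known ground truth.

## What it computes

**Shape.** Each frame's bead radii r(θ, φ) are fitted with real orthonormal
spherical harmonics up to degree l = 3,

  P_fit(θ, φ) = Σ_{l=0..3} Σ_{m=−l..l} c_lm Y_lm(θ, φ),

by linear least squares (the model is linear in c_lm, so the optimum is
exact). c₀₀/√(4π) is the mean radius; l = 1 captures hemisphere shifts,
l = 2 flattening/elongation, l = 3 higher deformations. Across a trajectory
the per-mode standard deviations and autocorrelation functions characterise
which undulation modes are active and how slowly they decorrelate — also a
practical convergence diagnostic for vesicle simulations.

**Packing.** MNND, the mean over lipids of the 3D distance to the nearest
other lipid COM, and MNNGC, its great-circle analogue on the reference
sphere (the curved-surface version of the in-plane nearest-neighbour
distance; it grows on smaller vesicles at equal chordal packing). Radial
distributions of phosphate beads about the bilayer mid-radius give
per-leaflet peaks, their separation (bilayer thickness) and spread.

**Annular shell & aggregation.** Lipids within 2 nm great-circle distance
of a protein surface are classified annular (strictly `< 2`), with
per-species annular fractions and contact residence times. Trimer–trimer
interfaces are detected from cross-trimer subunit COM distances (≤ 6.2 nm)
and classified tip-to-tip / tip-to-base / base-to-base by the contact
count (1 / 2-sharing / ≥3); a graph over trimers yields aggregation chains.

**Maps.** After removing a protein's great-circle transport and spin about
the surface normal, a gnomonic (cube-face) grid centred on the protein
accumulates leaflet height, bilayer thickness (outer − inner), and relative
lipid-species occupancy, with axes in summed great-circle nm.

**Motion coupling.** A molecule's displacement over Δt defines a
great-circle rotation axis n = (r_t × r_{t+Δt})/|…|; the direction
correlation between a lipid and a protein is cos θ = n_lipid · n_protein,
profiled against great-circle distance from the protein surface.

**Builder & generator.** `vesicle_builder` constructs two-leaflet vesicles
(lipid COMs Fibonacci-spaced by area-per-lipid on each leaflet sphere,
proteins at max–min separated sites, overlapping lipids removed).
`synthetic_trajectory` is a statistical emulator — great-circle Brownian
lipids, slowly rotating rigid trimers that drag an annular shell with
strength α, AR(1) shape modes with set SD and decay time — whose exact
realizations are returned as ground truth, so every analysis has a
closed-loop recovery test.

## Worked example

```python
import numpy as np
from vesisphere import (
    BuildSpec, DynamicsSpec, HarmonicMode, simulate,
    fit_trajectory, series_stats, neighbor_stats, annular_fraction_by_species,
)

build = BuildSpec(radius=10.0, species_mix=[("DSPC", 0.5), ("DLPC", 0.5)],
                  species_radial_offset={"DSPC": -0.3}, n_proteins=2, seed=1)
spec = DynamicsSpec(build=build, n_frames=100, dt=2.0, lipid_diffusion=0.01,
                    modes=[HarmonicMode(2, 0, 0.15, 40.0)],
                    coupling_strength=0.8, coupling_radius=2.0, seed=1)
res = simulate(spec)

fits = fit_trajectory(res.trajectory)
series = series_stats(fits)
print(f"mean radius (c00/sqrt(4pi)): {np.mean([f.radius_equivalent for f in fits]):.2f} nm")
print(f"fitted SD of c(2,0): {series.mode_sd(2, 0):.3f} nm  (injected realization SD "
      f"{res.truth.coefficient_series(2, 0).std(ddof=1):.3f} nm)")

stats = neighbor_stats(res.trajectory)
print(f"MNND  {stats.mnnd_mean:.3f} +/- {stats.mnnd_sd:.3f} nm")
print(f"MNNGC {stats.mnngc_mean:.3f} +/- {stats.mnngc_sd:.3f} nm")
```

prints

```
mean radius (c00/sqrt(4pi)): 10.02 nm
fitted SD of c(2,0): 0.106 nm  (injected realization SD 0.109 nm)
MNND  0.454 +/- 0.036 nm
MNNGC 0.405 +/- 0.041 nm
```

The fitted l = 2 mode SD tracks the injected AR(1) realization to ~3%. The
100-frame, ~4,000-lipid trajectory is a 10 nm vesicle with two trimeric
inclusions; the DSPC COM sits 0.3 nm deeper than DLPC, and lipids within
2 nm of a protein are 80%-dragged by its rotation. Here MNNGC < MNND
because the great-circle metric projects away that 0.3 nm radial species
offset; on single-offset systems the ordering reverses (arc ≥ chord).

A command-line layer exposes the same pipeline on files
(GRO/PDB single frames, XTC or multi-frame GRO trajectories, with a small
declarative topology file assigning bead roles):

```bash
vesisphere build --radius 10 --mix DSPC:0.5,DLPC:0.5 --n-proteins 2 --out ves.gro
vesisphere simulate --radius 10 --n-frames 100 --mode 2,0,0.15,40 \
    --out traj.xtc --frame0 frame0.gro --truth truth.csv
vesisphere harmonics --traj traj.xtc --top frame0.top --frame0 frame0.gro --out coeffs.csv
vesisphere packing   --traj traj.xtc --top frame0.top --frame0 frame0.gro --out packing.csv
vesisphere aggregate --traj traj.xtc --top frame0.top --frame0 frame0.gro --out interfaces.csv
vesisphere maps      --traj traj.xtc --top frame0.top --frame0 frame0.gro \
    --protein 0 --out-dir maps/
vesisphere dircorr   --traj traj.xtc --top frame0.top --frame0 frame0.gro --out dircorr.csv
```

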