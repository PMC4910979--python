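"""Construct initial vesicle configurations.

Lipid centres of mass are placed on ideal spheres (one per leaflet), spaced
according to the fluid-phase area per lipid: a leaflet of radius r holds
round(4*pi*r^2 / APL) lipids, laid out on a Fibonacci lattice so the spacing
is quasi-uniform and the construction is deterministic. Rigid trimeric
protein inclusions are inserted at positions maximising their minimum
pairwise great-circle separation (exact symmetric arrangements for small
counts, Fibonacci lattice otherwise), and lipids overlapping the inserted
proteins are removed.

Bead-level lipid and protein geometry comes from simple internal templates —
straight-chain lipids and a three-subunit barrel-like inclusion — since the
analyses consume only centres of mass, headgroup beads and protein beads,
not force-field detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Role, Topology, VesicleFrame

__all__ = [
    "BuildSpec",
    "BuildReport",
    "fibonacci_sphere",
    "protein_sites",
    "lipid_template",
    "trimer_template",
    "place_lipids",
    "insert_proteins",
    "build_vesicle",
    "build_topology",
]

#: default fluid-phase area per lipid (nm^2) for coarse-grained PC/PE-like lipids
DEFAULT_APL = 0.64

#: tail bead counts of the built-in straight-chain lipid templates
_TAIL_BEADS = {"DLPC": 2, "POPE": 3, "POPG": 3, "DSPC": 4}
_BEAD_SPACING = 0.3  # nm between consecutive beads along the lipid axis


@dataclass
class BuildSpec:
    """Parameters of a vesicle construction.

    ``radius`` is the sphere at the lipid COM mid-plane (nm). ``species_mix``
    lists (species, fraction) with fractions summing to 1. ``leaflet_offset``
    is the radial distance (nm) from the mid-plane to each leaflet's COM
    sphere (outer at radius + offset, inner at radius - offset).
    ``species_radial_offset`` shifts a species' COM radially inside its
    leaflet (negative = deeper toward the bilayer centre), emulating
    tail-length mismatch.
    """

    radius: float
    species_mix: list[tuple[str, float]] = field(
        default_factory=lambda: [("POPE", 0.75), ("POPG", 0.25)]
    )
    area_per_lipid: dict[str, float] | float = DEFAULT_APL
    leaflet_offset: float = 1.0
    species_radial_offset: dict[str, float] = field(default_factory=dict)
    n_proteins: int = 0
    overlap_cutoff: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.species_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, expected 1")
        if self.overlap_cutoff <= 0:
            raise ValueError("overlap_cutoff must be > 0")
        if self.radius <= self.leaflet_offset:
            raise ValueError("radius too small for two leaflets at this offset")

    def mean_apl(self) -> float:
        if isinstance(self.area_per_lipid, (int, float)):
            apl = float(self.area_per_lipid)
            if apl <= 0:
                raise ValueError("area_per_lipid must be > 0")
            return apl
        apl = sum(f * self.area_per_lipid[sp] for sp, f in self.species_mix)
        if apl <= 0 or any(v <= 0 for v in self.area_per_lipid.values()):
            raise ValueError("area_per_lipid must be > 0")
        return apl


@dataclass
class BuildReport:
    """What the builder did: per-leaflet counts and overlap removals."""

    n_outer: int
    n_inner: int
    n_removed_overlap: int = 0
    n_proteins: int = 0


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci / golden-spiral lattice)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def leaflet_count(r_leaflet: float, apl: float) -> int:
    """Lipids a leaflet holds: round(4*pi*r^2 / APL)."""
    if apl <= 0:
        raise ValueError("area_per_lipid must be > 0")
    return int(round(4.0 * np.pi * r_leaflet**2 / apl))


def protein_sites(n: int) -> np.ndarray:
    """Unit directions for n inclusions, maximising minimum separation.

    Exact symmetric arrangements for n <= 6 (antipodal pair, equatorial
    triangle, tetrahedron, bipyramid, octahedron); Fibonacci lattice beyond.
    """
    if n < 1:
        raise ValueError("n_proteins must be >= 1")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    if n == 2:
        return np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    if n == 3:
        ang = 2.0 * np.pi * np.arange(3) / 3.0
        return np.column_stack([np.cos(ang), np.sin(ang), np.zeros(3)])
    if n == 4:
        return np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
    if n == 5:
        ang = 2.0 * np.pi * np.arange(3) / 3.0
        eq = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(3)])
        return np.vstack([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0], eq])
    if n == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    return fibonacci_sphere(n)


def lipid_template(species: str) -> list[tuple[str, Role, float]]:
    """(bead_name, role, axial offset nm) for a straight-chain lipid.

    Offsets run along the lipid axis (positive toward the headgroup) and are
    centred so the equal-mass COM sits at zero.
    """
    n_tail = _TAIL_BEADS.get(species, 3)
    beads: list[tuple[str, Role]] = [("PO4", Role.HEADGROUP), ("GL1", Role.LINKER)]
    beads += [(f"C{k + 1}A", Role.TAIL) for k in range(n_tail)]
    offsets = -_BEAD_SPACING * np.arange(len(beads), dtype=float)
    offsets -= offsets.mean()
    return [(name, role, float(off)) for (name, role), off in zip(beads, offsets)]


def trimer_template(
    span: float = 4.2, subunit_radius: float = 1.2, n_layers: int = 7
) -> list[tuple[str, Role, np.ndarray, int]]:
    """Bead layout of a rigid three-subunit membrane inclusion.

    Returns (bead_name, role, offset-from-COM, subunit index 0..2). Each
    subunit is a column of backbone beads spanning ``span`` nm along the
    inclusion axis at ``subunit_radius`` from it, decorated with two
    sidechain beads; subunits sit 120 degrees apart. The COM is at zero and
    the axis along +z, so placing the COM on the lipid-COM sphere makes the
    inclusion span the bilayer.
    """
    beads: list[tuple[str, Role, np.ndarray, int]] = []
    zs = np.linspace(-span / 2.0, span / 2.0, n_layers)
    for s in range(3):
        gamma = 2.0 * np.pi * s / 3.0
        cx, cy = subunit_radius * np.cos(gamma), subunit_radius * np.sin(gamma)
        for j, z in enumerate(zs):
            beads.append((f"BB{j + 1}", Role.PROTEIN_BACKBONE, np.array([cx, cy, z]), s))
        for j, z in enumerate((-span / 4.0, span / 4.0)):
            sx = 1.5 * subunit_radius * np.cos(gamma)
            sy = 1.5 * subunit_radius * np.sin(gamma)
            beads.append((f"SC{j + 1}", Role.PROTEIN_SIDECHAIN, np.array([sx, sy, z]), s))
    offsets = np.stack([b[2] for b in beads])
    com = offsets.mean(axis=0)
    return [(name, role, off - com, s) for (name, role, off, s) in beads]


def _rotation_to(axis_to: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying +z to the unit vector ``axis_to``."""
    z = np.array([0.0, 0.0, 1.0])
    axis_to = axis_to / np.linalg.norm(axis_to)
    c = float(np.dot(z, axis_to))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis_to)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _spin_matrix(u: np.ndarray, angle: float) -> np.ndarray:
    """Rotation by ``angle`` about unit axis ``u`` (Rodrigues)."""
    ux = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * ux + (1 - np.cos(angle)) * (ux @ ux)


def place_lipids(spec: BuildSpec) -> VesicleFrame:
    """Two-leaflet lipid placement on the spec's COM spheres.

    Outer-leaflet lipids point their headgroups outward, inner-leaflet
    inward. Species are assigned to sites by a seeded random permutation so
    the leaflet composition matches the mix within rounding. Deterministic
    for a fixed seed.
    """
    apl = spec.mean_apl()
    rng = np.random.default_rng(spec.seed)
    positions, mol_ids, species_arr, roles, names = [], [], [], [], []
    mol_id = 0
    counts = {}
    for leaflet, sign in (("outer", +1.0), ("inner", -1.0)):
        r_leaflet = spec.radius + sign * spec.leaflet_offset
        if r_leaflet <= 0:
            raise ValueError("radius too small for two leaflets")
        n = leaflet_count(r_leaflet, apl)
        counts[leaflet] = n
        units = fibonacci_sphere(n)
        site_species = _assign_species(spec.species_mix, n, rng)
        for u, sp in zip(units, site_species):
            template = lipid_template(sp)
            r_com = r_leaflet + spec.species_radial_offset.get(sp, 0.0)
            head_dir = sign * u  # outward for outer leaflet, inward for inner
            for bead_name, role, off in template:
                positions.append(r_com * u + off * head_dir)
                mol_ids.append(mol_id)
                species_arr.append(sp)
                roles.append(role.value)
                names.append(bead_name)
            mol_id += 1
    frame = VesicleFrame(
        positions=np.asarray(positions),
        molecule_ids=np.asarray(mol_ids),
        species=np.asarray(species_arr, dtype=object),
        roles=np.asarray(roles, dtype=object),
        bead_names=np.asarray(names, dtype=object),
        time=0.0,
    )
    frame._build_counts = counts  # type: ignore[attr-defined]
    return frame


def _assign_species(mix: list[tuple[str, float]], n: int, rng: np.random.Generator) -> list[str]:
    labels: list[str] = []
    for sp, frac in mix:
        labels.extend([sp] * int(round(frac * n)))
    while len(labels) < n:
        labels.append(mix[0][0])
    labels = labels[:n]
    perm = rng.permutation(n)
    return [labels[i] for i in perm]


def insert_proteins(
    frame: VesicleFrame, spec: BuildSpec
) -> tuple[VesicleFrame, Topology, BuildReport]:
    """Insert ``spec.n_proteins`` rigid trimers and remove overlapping lipids.

    Trimer COMs go on the lipid mid-plane sphere at the max-min separated
    sites of :func:`protein_sites`, each with a seeded random spin about its
    local surface normal. Any lipid with a bead within ``overlap_cutoff`` of
    a protein bead is removed whole. Raises when the requested count forces
    the inclusions themselves to overlap.
    """
    if spec.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1 for insertion")
    rng = np.random.default_rng(spec.seed + 1)
    template = trimer_template()
    footprint = max(np.linalg.norm(off[:2]) for _, _, off, _ in template)
    sites = protein_sites(spec.n_proteins)
    if spec.n_proteins > 1:
        dots = sites @ sites.T
        np.fill_diagonal(dots, -1.0)
        min_sep = spec.radius * np.arccos(np.clip(dots.max(), -1.0, 1.0))
        if min_sep < 2.0 * footprint:
            raise ValueError(
                f"{spec.n_proteins} proteins cannot fit on radius {spec.radius} nm "
                f"without overlapping (min separation {min_sep:.2f} nm); "
                "reduce n_proteins or increase radius"
            )
    next_mol = int(frame.molecule_ids.max()) + 1 if frame.n_beads else 0
    positions, mol_ids, species_arr, roles, names = [], [], [], [], []
    trimers: dict[int, tuple[int, int, int]] = {}
    for tid, u in enumerate(sites):
        rot = _spin_matrix(u, rng.uniform(0.0, 2.0 * np.pi)) @ _rotation_to(u)
        com = spec.radius * u
        subunit_mols = tuple(next_mol + s for s in range(3))
        trimers[tid] = subunit_mols  # type: ignore[assignment]
        next_mol += 3
        for bead_name, role, off, s in template:
            positions.append(com + rot @ off)
            mol_ids.append(subunit_mols[s])
            species_arr.append("OMPF")
            roles.append(role.value)
            names.append(bead_name)
    protein_pos = np.asarray(positions)

    tree = cKDTree(protein_pos)
    close = tree.query_ball_point(frame.positions, spec.overlap_cutoff)
    clashing_beads = np.asarray([len(c) > 0 for c in close], dtype=bool)
    clashing_mols = np.unique(frame.molecule_ids[clashing_beads])
    keep = ~np.isin(frame.molecule_ids, clashing_mols)

    merged = VesicleFrame(
        positions=np.vstack([frame.positions[keep], protein_pos]),
        molecule_ids=np.concatenate([frame.molecule_ids[keep], np.asarray(mol_ids)]),
        species=np.concatenate([frame.species[keep], np.asarray(species_arr, dtype=object)]),
        roles=np.concatenate([frame.roles[keep], np.asarray(roles, dtype=object)]),
        bead_names=np.concatenate([frame.bead_names[keep], np.asarray(names, dtype=object)]),
        time=frame.time,
        box=frame.box,
    )
    counts = getattr(frame, "_build_counts", {"outer": 0, "inner": 0})
    report = BuildReport(
        n_outer=counts.get("outer", 0),
        n_inner=counts.get("inner", 0),
        n_removed_overlap=int(len(clashing_mols)),
        n_proteins=spec.n_proteins,
    )
    topology = build_topology(spec, trimers)
    return merged, topology, report


def build_topology(spec: BuildSpec, trimers: dict | None = None) -> Topology:
    """Topology (bead roles + trimer roster) matching the builder's templates."""
    top = Topology()
    for sp, _ in spec.species_mix:
        for bead_name, role, _off in lipid_template(sp):
            top.bead_roles[(sp, bead_name)] = role
    if spec.n_proteins > 0 or trimers:
        top.protein_species.add("OMPF")
        top.bead_roles[("OMPF", "BB*")] = Role.PROTEIN_BACKBONE
        top.bead_roles[("OMPF", "SC*")] = Role.PROTEIN_SIDECHAIN
    top.solvent_species.update({"W", "ION"})
    if trimers:
        top.trimers.update(trimers)
    return top


def build_vesicle(spec: BuildSpec) -> tuple[VesicleFrame, Topology, BuildReport]:
    """Full construction: lipid placement plus optional protein insertion."""
    frame = place_lipids(spec)
    if spec.n_proteins >= 1:
        return insert_proteins(frame, spec)
    counts = getattr(frame, "_build_counts", {"outer": 0, "inner": 0})
    report = BuildReport(n_outer=counts["outer"], n_inner=counts["inner"])
    return frame, build_topology(spec), report
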