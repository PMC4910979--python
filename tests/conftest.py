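"""Shared fixtures: tiny hand-built frames and topology files."""

from __future__ import annotations

import numpy as np
import pytest

from vesisphere.model_io import Role, Topology, Trajectory, VesicleFrame
from vesisphere.vesicle_builder import fibonacci_sphere


def two_bead_lipid_frame(
    head_radii: np.ndarray,
    units: np.ndarray,
    leaflet_sign: np.ndarray,
    species: list[str] | None = None,
    time: float = 0.0,
    tail_gap: float = 0.6,
    extra_positions: np.ndarray | None = None,
    extra_species: str = "OMPF",
) -> VesicleFrame:
    """Frame of two-bead lipids: head at ``head_radii``, tail 0.6 nm away.

    ``leaflet_sign`` +1 puts the tail radially inward of the head (outer
    leaflet), -1 outward (inner leaflet). ``extra_positions`` appends protein
    backbone beads as one three-"subunit" molecule triple.
    """
    n = len(head_radii)
    if species is None:
        species = ["POPE"] * n
    head_radii = np.asarray(head_radii, dtype=float)
    leaflet_sign = np.asarray(leaflet_sign, dtype=float)
    pos_pairs = np.empty((n, 2, 3))
    pos_pairs[:, 0] = head_radii[:, None] * units
    pos_pairs[:, 1] = (head_radii - leaflet_sign * tail_gap)[:, None] * units
    positions = list(pos_pairs.reshape(-1, 3))
    mols = np.repeat(np.arange(n), 2).tolist()
    specs = np.repeat(np.asarray(species, dtype=object), 2).tolist()
    roles = [Role.HEADGROUP.value, Role.TAIL.value] * n
    names = ["PO4", "C1A"] * n
    if extra_positions is not None:
        base = n
        per = max(len(extra_positions) // 3, 1)
        for j, p in enumerate(extra_positions):
            positions.append(p)
            mols.append(base + min(j // per, 2))
            specs.append(extra_species)
            roles.append(Role.PROTEIN_BACKBONE.value)
            names.append(f"BB{j + 1}")
    return VesicleFrame(
        positions=np.asarray(positions),
        molecule_ids=np.asarray(mols),
        species=np.asarray(specs, dtype=object),
        roles=np.asarray(roles, dtype=object),
        bead_names=np.asarray(names, dtype=object),
        time=time,
    )


def concentric_shell_frame(
    n_per_leaflet: int = 400,
    r_inner: float = 30.7,
    r_outer: float = 35.0,
    time: float = 0.0,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    radial_bump=None,
    bump_inner=None,
    bump_outer=None,
    units: np.ndarray | None = None,
    extra_positions: np.ndarray | None = None,
) -> VesicleFrame:
    """Two delta shells of headgroup beads at the given radii.

    ``radial_bump(units) -> per-point radial shift`` perturbs both shells
    (``bump_inner``/``bump_outer`` perturb one shell only); ``noise`` adds
    i.i.d. radial jitter. ``units`` overrides the default Fibonacci lattice
    (e.g. to emulate lateral motion across frames).
    """
    if units is None:
        units = fibonacci_sphere(n_per_leaflet)
    r_in = np.full(n_per_leaflet, r_inner)
    r_out = np.full(n_per_leaflet, r_outer)
    if radial_bump is not None:
        r_in = r_in + radial_bump(units)
        r_out = r_out + radial_bump(units)
    if bump_inner is not None:
        r_in = r_in + bump_inner(units)
    if bump_outer is not None:
        r_out = r_out + bump_outer(units)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        r_in = r_in + noise * rng.standard_normal(n_per_leaflet)
        r_out = r_out + noise * rng.standard_normal(n_per_leaflet)
    all_units = np.vstack([units, units])
    radii = np.concatenate([r_out, r_in])
    signs = np.concatenate([np.ones(n_per_leaflet), -np.ones(n_per_leaflet)])
    return two_bead_lipid_frame(
        radii, all_units, signs, time=time, extra_positions=extra_positions
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_topology() -> Topology:
    top = Topology()
    for sp in ("POPE", "POPG", "DSPC", "DLPC"):
        top.bead_roles[(sp, "PO4")] = Role.HEADGROUP
        top.bead_roles[(sp, "GL1")] = Role.LINKER
        top.bead_roles[(sp, "C*")] = Role.TAIL
    top.bead_roles[("OMPF", "BB*")] = Role.PROTEIN_BACKBONE
    top.bead_roles[("OMPF", "SC*")] = Role.PROTEIN_SIDECHAIN
    top.protein_species.add("OMPF")
    top.solvent_species.update({"W", "ION"})
    return top


@pytest.fixture
def topology_file(tmp_path, simple_topology):
    lines = ["# test topology"]
    for (sp, name), role in simple_topology.bead_roles.items():
        lines.append(f"bead {sp} {name} {role.value}")
    lines.append("protein OMPF")
    lines.append("solvent W ION")
    path = tmp_path / "system.top"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_trajectory(frames: list[VesicleFrame], dt: float = 2.0) -> Trajectory:
    for k, fr in enumerate(frames):
        fr.time = k * dt
    return Trajectory(frames=frames, dt=dt)
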