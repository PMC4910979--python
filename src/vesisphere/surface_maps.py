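"""Protein-centred maps of leaflet height, bilayer thickness, and occupancy.

The protein's own motion over the vesicle — great-circle transport of its
COM and spin about the local surface normal — is removed frame by frame with
a pure rotation about the vesicle centre, so that the protein sits at its
frame-0 position and orientation in every aligned frame. A gnomonic grid
centred on the protein then accumulates, per cell: the mean radial distance
of headgroup beads of a leaflet (height map), outer minus inner height
(thickness map), or the relative frequency of each lipid species
(occupancy map). Cells never visited are flagged missing (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model_io import Role, Topology, Trajectory, VesicleFrame
from .spherical_geometry import (
    ProjectionGrid,
    SphereFrameRef,
    project_to_grid,
    weighted_center_and_radius,
)

__all__ = [
    "MapKind",
    "SurfaceMap",
    "RigidTransform",
    "remove_protein_motion",
    "assign_leaflets",
    "protein_grid",
    "leaflet_height_map",
    "thickness_map",
    "occupancy_map",
]


class MapKind(str, Enum):
    INNER_HEIGHT = "inner_height"
    OUTER_HEIGHT = "outer_height"
    THICKNESS = "thickness"
    OCCUPANCY = "occupancy"


@dataclass
class SurfaceMap:
    """2D grid of per-cell values with observation counts.

    ``values`` is (n, n) in nm for heights/thickness or a fraction in [0, 1]
    for occupancy; NaN marks cells with no observations. Axes are labelled by
    ``grid.edge_coordinates()`` (summed great-circle nm).
    """

    grid: ProjectionGrid
    values: np.ndarray
    counts: np.ndarray
    kind: MapKind

    def __post_init__(self) -> None:
        if self.kind is MapKind.OCCUPANCY:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("occupancy values must lie in [0, 1]")

    @property
    def missing(self) -> np.ndarray:
        return self.counts == 0


@dataclass
class RigidTransform:
    """Rotation about the vesicle centre applied to one frame during alignment."""

    rotation: np.ndarray  # (3, 3)
    center: np.ndarray  # (3,) the frame's vesicle centre

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return (positions - self.center) @ self.rotation.T + self.center


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector a onto unit vector b."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        # antipodal: rotate by pi about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    v = np.cross(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def _protein_rows(frame: VesicleFrame, topology: Topology, trimer_id: int) -> np.ndarray:
    subunits = list(topology.trimers[trimer_id])
    rows = np.flatnonzero(np.isin(frame.molecule_ids, subunits))
    if rows.size == 0:
        raise KeyError(f"trimer {trimer_id} not present in frame")
    return rows


def _inplane_axis(positions: np.ndarray, center: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Protein in-plane orientation at surface normal ``u``.

    The first principal axis of the bead cloud, projected to the tangent
    plane and sign-fixed by the first bead. A transmembrane inclusion's
    principal axis is nearly radial, leaving a noise-dominated projection; in
    that regime the tangential COM offset of the first third of the beads
    (the first subunit) is used instead — it breaks the trimer's three-fold
    symmetry deterministically and averages bead-level noise.
    """
    rel = positions - center
    com = rel.mean(axis=0)
    centred = rel - com
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    sign_ref = rel[0] - com
    if np.dot(axis, sign_ref) < 0:
        axis = -axis
    del svals
    proj = axis - np.dot(axis, u) * u
    if np.linalg.norm(proj) < 0.25:  # axis within ~15 deg of radial
        first_subunit = rel[: max(len(rel) // 3, 1)].mean(axis=0) - com
        proj = first_subunit - np.dot(first_subunit, u) * u
    norm = np.linalg.norm(proj)
    if norm < 1e-9:
        raise ValueError("protein orientation undefined (degenerate geometry)")
    return proj / norm


def remove_protein_motion(
    traj: Trajectory, topology: Topology, trimer_id: int
) -> tuple[Trajectory, list[RigidTransform]]:
    """Align every frame so the chosen trimer matches its frame-0 placement.

    Each frame is rotated about its own vesicle centre: first the minimal
    rotation carrying the protein COM direction onto frame 0's, then a spin
    about that direction aligning the protein's in-plane orientation. The
    transform is a pure rotation, so all radial distances are preserved
    exactly.
    """
    frames = traj.frames
    ref0 = weighted_center_and_radius(frames[0])
    rows0 = _protein_rows(frames[0], topology, trimer_id)
    com0 = frames[0].positions[rows0].mean(axis=0)
    if np.linalg.norm(com0 - ref0.center) < 1e-9:
        raise ValueError("protein COM at vesicle centre: surface normal undefined")
    u0 = (com0 - ref0.center) / np.linalg.norm(com0 - ref0.center)
    axis0 = _inplane_axis(frames[0].positions[rows0], ref0.center, u0)

    aligned = []
    transforms = []
    for frame in frames:
        ref = weighted_center_and_radius(frame)
        rows = _protein_rows(frame, topology, trimer_id)
        com = frame.positions[rows].mean(axis=0)
        v = com - ref.center
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError("protein COM at vesicle centre: surface normal undefined")
        r1 = _rotation_between(v / norm, u0)
        moved = (frame.positions[rows] - ref.center) @ r1.T
        axis_t = _inplane_axis(moved + ref.center, ref.center, u0)
        # signed spin angle about u0 from axis_t to axis0
        cos_a = float(np.clip(np.dot(axis_t, axis0), -1.0, 1.0))
        sin_a = float(np.dot(np.cross(axis_t, axis0), u0))
        spin = _axis_angle(u0, float(np.arctan2(sin_a, cos_a)))
        transform = RigidTransform(rotation=spin @ r1, center=ref.center.copy())
        new_frame = VesicleFrame(
            positions=transform.apply(frame.positions),
            molecule_ids=frame.molecule_ids,
            species=frame.species,
            roles=frame.roles,
            bead_names=frame.bead_names,
            time=frame.time,
            box=frame.box,
        )
        aligned.append(new_frame)
        transforms.append(transform)
    return Trajectory(frames=aligned, dt=traj.dt), transforms


def assign_leaflets(frame: VesicleFrame, ref: SphereFrameRef | None = None) -> dict[int, str]:
    """Map lipid molecule id -> "outer"/"inner".

    A lipid is in the outer leaflet iff its headgroup bead sits radially
    farther from the vesicle centre than its terminal tail bead — robust to
    undulations, unlike a fixed radius threshold.
    """
    if ref is None:
        ref = weighted_center_and_radius(frame)
    lmask = frame.lipid_mask
    mols = frame.molecule_ids[lmask]
    pos = frame.positions[lmask]
    roles = np.asarray(frame.roles[lmask])
    radii = np.linalg.norm(pos - ref.center, axis=1)
    uniq, inverse = np.unique(mols, return_inverse=True)
    n = len(uniq)

    is_head = roles == Role.HEADGROUP.value
    head_sum = np.bincount(inverse[is_head], weights=radii[is_head], minlength=n)
    head_cnt = np.bincount(inverse[is_head], minlength=n)
    head_mean = np.divide(head_sum, head_cnt, out=np.full(n, np.nan), where=head_cnt > 0)

    is_tail = roles == Role.TAIL.value
    # terminal tail bead: the tail bead farthest (radially) from the headgroup
    dev = np.abs(radii[is_tail] - head_mean[inverse[is_tail]])
    tail_inv = inverse[is_tail]
    order = np.lexsort((-dev, tail_inv))
    tail_tip_radius = np.full(n, np.nan)
    sorted_inv = tail_inv[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_inv[1:] != sorted_inv[:-1]
    tail_tip_radius[sorted_inv[first]] = radii[is_tail][order][first]

    out: dict[int, str] = {}
    for j, mid in enumerate(uniq):
        if head_cnt[j] == 0:
            continue
        if np.isnan(tail_tip_radius[j]):
            out[int(mid)] = "outer"
        else:
            out[int(mid)] = "outer" if head_mean[j] > tail_tip_radius[j] else "inner"
    return out


def protein_grid(
    aligned: Trajectory,
    topology: Topology,
    trimer_id: int,
    cell_edge: float = 0.5,
    n_cells: int = 24,
) -> ProjectionGrid:
    """Gnomonic grid centred on the (aligned) trimer's frame-0 COM.

    The grid's in-plane orientation is anchored to the protein's own
    in-plane axis, so maps are expressed in the protein frame and are
    invariant under a rigid global rotation of the input.
    """
    frame0 = aligned.frames[0]
    ref0 = weighted_center_and_radius(frame0)
    rows = _protein_rows(frame0, topology, trimer_id)
    com = frame0.positions[rows].mean(axis=0)
    u = ref0.unit(com)
    axis = _inplane_axis(frame0.positions[rows], ref0.center, u)
    return ProjectionGrid.centered_on(
        com, ref0, cell_edge=cell_edge, n_cells=n_cells, axis_u=axis
    )


def leaflet_height_map(
    aligned: Trajectory | list[VesicleFrame],
    grid: ProjectionGrid,
    leaflet: str = "outer",
) -> SurfaceMap:
    """Mean radial distance of a leaflet's headgroup beads, per grid cell.

    For each frame, headgroup beads of lipids in the chosen leaflet are
    projected onto the grid and each occupied cell records their mean radial
    distance from that frame's vesicle centre; cell values are then averaged
    over the frames in which the cell was occupied.
    """
    if leaflet not in ("outer", "inner"):
        raise ValueError("leaflet must be 'outer' or 'inner'")
    frames = aligned.frames if isinstance(aligned, Trajectory) else aligned
    n = grid.n_cells
    total = np.zeros((n, n))
    frames_seen = np.zeros((n, n))
    obs = np.zeros((n, n), dtype=np.int64)
    for frame in frames:
        ref = weighted_center_and_radius(frame)
        leaflets = assign_leaflets(frame, ref)
        hmask = frame.headgroup_mask
        mols = frame.molecule_ids[hmask]
        keep = np.asarray([leaflets.get(int(m)) == leaflet for m in mols], dtype=bool)
        pos = frame.positions[hmask][keep]
        if len(pos) == 0:
            continue
        radii = np.linalg.norm(pos - ref.center, axis=1)
        idx, _ = project_to_grid(pos, ref, grid)
        ok = idx[:, 0] >= 0
        if not ok.any():
            continue
        flat = idx[ok, 0] * n + idx[ok, 1]
        sums = np.bincount(flat, weights=radii[ok], minlength=n * n)
        cnts = np.bincount(flat, minlength=n * n)
        occupied = cnts > 0
        frame_mean = np.zeros(n * n)
        frame_mean[occupied] = sums[occupied] / cnts[occupied]
        total += np.where(occupied, frame_mean, 0.0).reshape(n, n)
        frames_seen += occupied.reshape(n, n)
        obs += cnts.reshape(n, n).astype(np.int64)
    values = np.full((n, n), np.nan)
    seen = frames_seen > 0
    values[seen] = total[seen] / frames_seen[seen]
    kind = MapKind.OUTER_HEIGHT if leaflet == "outer" else MapKind.INNER_HEIGHT
    return SurfaceMap(grid=grid, values=values, counts=obs, kind=kind)


def thickness_map(inner: SurfaceMap, outer: SurfaceMap) -> SurfaceMap:
    """Per-cell bilayer thickness: outer height minus inner height.

    Missing cells in either input stay missing. The identity
    thickness + inner = outer holds cell-wise by construction.
    """
    if inner.grid is not outer.grid and (
        inner.grid.n_cells != outer.grid.n_cells
        or inner.grid.cell_edge != outer.grid.cell_edge
        or not np.allclose(inner.grid.origin_unit, outer.grid.origin_unit)
    ):
        raise ValueError("thickness_map requires height maps on the same grid")
    values = outer.values - inner.values
    counts = np.minimum(inner.counts, outer.counts)
    values[counts == 0] = np.nan
    return SurfaceMap(grid=inner.grid, values=values, counts=counts, kind=MapKind.THICKNESS)


def occupancy_map(
    aligned: Trajectory | list[VesicleFrame],
    grid: ProjectionGrid,
    species: list[str],
    leaflet: str = "outer",
) -> dict[str, SurfaceMap]:
    """Relative per-cell frequency of each lipid species, by lipid COM.

    In every visited cell the species fractions sum to 1; unvisited cells
    are missing (NaN). Restrict the time window by slicing the trajectory
    before calling.
    """
    if len(species) < 2:
        raise ValueError("relative occupancy needs at least 2 species")
    frames = aligned.frames if isinstance(aligned, Trajectory) else aligned
    n = grid.n_cells
    counts = {sp: np.zeros((n, n), dtype=np.int64) for sp in species}
    for frame in frames:
        ref = weighted_center_and_radius(frame)
        leaflets = assign_leaflets(frame, ref)
        ids, coms = frame.lipid_coms()
        sp_table = frame.lipid_species_table()
        keep = np.asarray(
            [leaflets.get(int(i)) == leaflet and sp_table[int(i)] in counts for i in ids],
            dtype=bool,
        )
        if not keep.any():
            continue
        idx, _ = project_to_grid(coms[keep], ref, grid)
        kept_ids = ids[keep]
        ok = idx[:, 0] >= 0
        sp_arr = np.asarray([sp_table[int(m)] for m in kept_ids[ok]], dtype=object)
        flat = idx[ok, 0] * n + idx[ok, 1]
        for sp in counts:
            sel = sp_arr == sp
            if sel.any():
                counts[sp] += np.bincount(flat[sel], minlength=n * n).reshape(n, n).astype(np.int64)
    total = sum(counts.values())
    out = {}
    for sp in species:
        values = np.full((n, n), np.nan)
        visited = total > 0
        values[visited] = counts[sp][visited] / total[visited]
        out[sp] = SurfaceMap(grid=grid, values=values, counts=counts[sp], kind=MapKind.OCCUPANCY)
    return out
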