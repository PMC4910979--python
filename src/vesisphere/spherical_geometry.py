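"""Great-circle mathematics and sphere-surface grid projection.

All downstream analyses reduce vesicle geometry to a reference sphere: the
equal-mass centre of the selected beads and their mean radial distance. Arc
lengths between beads are measured on that sphere after radially projecting
both points onto it, since beads sit at slightly different radii. The
protein-centred maps use an equiangular gnomonic (cube-face) grid whose axes
are labelled by cumulative great-circle distance along the grid edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import VesicleFrame

__all__ = [
    "SphereFrameRef",
    "ProjectionGrid",
    "weighted_center_and_radius",
    "great_circle_distance",
    "rotation_axis",
    "direction_correlation",
    "project_to_grid",
    "tangent_basis",
]


@dataclass(frozen=True)
class SphereFrameRef:
    """Reference sphere of one frame: bilayer centre (nm) and mean radius (nm)."""

    center: np.ndarray
    mean_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be > 0")

    def unit(self, points: np.ndarray) -> np.ndarray:
        """Radial unit vectors of ``points`` (…,3) about the centre."""
        v = np.asarray(points, dtype=float) - self.center
        norms = np.linalg.norm(v, axis=-1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("point coincides with the sphere centre")
        return v / norms


def weighted_center_and_radius(
    frame: VesicleFrame | np.ndarray, selection: np.ndarray | None = None
) -> SphereFrameRef:
    """Centre of mass and mean radius of the selected beads.

    MARTINI beads are treated as equal-mass, so the weighted COM is the
    arithmetic mean and the weighted average radius is the mean distance of
    the selected beads to that centre. ``selection`` is a boolean mask; by
    default all lipid beads of a frame are used (all rows of a bare array).
    """
    if isinstance(frame, VesicleFrame):
        pos = frame.positions
        if selection is None:
            selection = frame.lipid_mask
    else:
        pos = np.asarray(frame, dtype=float)
    if selection is not None:
        pos = pos[np.asarray(selection, dtype=bool)]
    if len(pos) == 0:
        raise ValueError("selection is empty")
    center = pos.mean(axis=0)
    radius = float(np.linalg.norm(pos - center, axis=1).mean())
    return SphereFrameRef(center=center, mean_radius=max(radius, np.finfo(float).tiny))


def great_circle_distance(
    a: np.ndarray, b: np.ndarray, ref: SphereFrameRef
) -> np.ndarray | float:
    """Arc length (nm) between ``a`` and ``b`` on the reference sphere.

    Both points are radially projected onto ``ref.mean_radius`` first; the
    result is ``R * angle`` with the angle computed via atan2 of cross/dot,
    which is stable for near-parallel and near-antipodal pairs. Broadcasts
    over leading axes.
    """
    ua = ref.unit(a)
    ub = ref.unit(b)
    cross = np.linalg.norm(np.cross(ua, ub), axis=-1)
    dot = np.sum(ua * ub, axis=-1)
    ang = np.arctan2(cross, dot)
    out = ref.mean_radius * ang
    return float(out) if np.ndim(out) == 0 else out


def rotation_axis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unit axis of the great-circle rotation carrying direction ``a`` to ``b``.

    Computed as (a x b)/|a x b|; orthogonal to both inputs, and antisymmetric
    under swapping the direction of travel. Raises for (anti)parallel inputs,
    whose rotation axis is undefined. Broadcasts over leading axes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-length input vector")
    cross = np.cross(a, b)
    nc = np.linalg.norm(cross, axis=-1)
    sin_theta = nc / (na * nb)
    if np.any(sin_theta < 1e-12):
        raise ValueError("rotation axis undefined for (anti)parallel vectors")
    return cross / nc[..., None]


def direction_correlation(n_i: np.ndarray, n_k: np.ndarray) -> np.ndarray | float:
    """cos(theta) between two rotation axes: the dot product of unit vectors."""
    n_i = np.asarray(n_i, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    for v in (n_i, n_k):
        norms = np.linalg.norm(v, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("direction_correlation requires unit vectors")
    out = np.sum(n_i * n_k, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangent directions at unit vector ``u``."""
    u = np.asarray(u, dtype=float)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


@dataclass
class ProjectionGrid:
    """Equiangular gnomonic grid on the sphere, centred on a reference point.

    The grid is the central portion of a cube-face projection: grid lines sit
    at equal steps of great-circle distance along the two edge directions, so
    a cell's nominal edge is ``cell_edge`` nm of arc. ``axis_u``/``axis_v``
    are the orthonormal tangent directions of the face at the reference point
    ``origin_unit`` (a unit vector from the sphere centre). The covered
    region is limited to half a cube face per side (|angle| <= 45 deg), i.e.
    at most half the sphere's surface in extent.
    """

    origin_unit: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    cell_edge: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.cell_edge <= 0:
            raise ValueError("cell_edge must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.origin_unit = np.asarray(self.origin_unit, dtype=float)
        self.origin_unit = self.origin_unit / np.linalg.norm(self.origin_unit)
        self.axis_u = np.asarray(self.axis_u, dtype=float)
        self.axis_v = np.asarray(self.axis_v, dtype=float)

    @classmethod
    def centered_on(
        cls,
        point: np.ndarray,
        ref: SphereFrameRef,
        cell_edge: float = 0.5,
        n_cells: int = 24,
        axis_u: np.ndarray | None = None,
    ) -> "ProjectionGrid":
        """Grid at ``point``; ``axis_u`` anchors the in-plane orientation
        (orthogonalised against the normal), defaulting to an arbitrary
        tangent direction."""
        u = ref.unit(point)
        if axis_u is None:
            e1, e2 = tangent_basis(u)
        else:
            e1 = np.asarray(axis_u, dtype=float)
            e1 = e1 - np.dot(e1, u) * u
            norm = np.linalg.norm(e1)
            if norm < 1e-9:
                raise ValueError("axis_u is (anti)parallel to the grid normal")
            e1 = e1 / norm
            e2 = np.cross(u, e1)
        grid = cls(origin_unit=u, axis_u=e1, axis_v=e2, cell_edge=cell_edge, n_cells=n_cells)
        half_angle = grid.half_extent / ref.mean_radius
        if half_angle > np.pi / 4 + 1e-12:
            raise ValueError(
                "grid extent exceeds half a cube face (45 deg half-angle); "
                "reduce n_cells or cell_edge"
            )
        return grid

    @property
    def half_extent(self) -> float:
        """Half the grid width as arc length (nm)."""
        return 0.5 * self.n_cells * self.cell_edge

    def edge_coordinates(self) -> np.ndarray:
        """Cell-centre coordinates (nm of summed great-circle distance)."""
        return (np.arange(self.n_cells) - (self.n_cells - 1) / 2.0) * self.cell_edge


def project_to_grid(
    points: np.ndarray, ref: SphereFrameRef, grid: ProjectionGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Assign points to grid cells; label coordinates by arc length.

    Returns ``(indices, coords)`` where ``indices`` is (n, 2) int cell indices
    (``-1`` marks points outside the covered region — flagged, never dropped)
    and ``coords`` is (n, 2) float arc-length coordinates (nm) along the two
    edge directions, measured as great-circle distance from the grid centre
    (NaN outside the front hemisphere).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = ref.unit(pts)
    w = u @ grid.origin_unit
    tu = np.full(len(pts), np.nan)
    tv = np.full(len(pts), np.nan)
    front = w > 1e-9
    # gnomonic tangent-plane coordinates, then equiangular relabelling:
    # arc along an edge s = R * atan(t)
    tu[front] = (u[front] @ grid.axis_u) / w[front]
    tv[front] = (u[front] @ grid.axis_v) / w[front]
    su = ref.mean_radius * np.arctan(tu)
    sv = ref.mean_radius * np.arctan(tv)
    coords = np.stack([su, sv], axis=1)

    half = grid.half_extent
    iu = np.floor((su + half) / grid.cell_edge).astype(float)
    iv = np.floor((sv + half) / grid.cell_edge).astype(float)
    ok = (
        front
        & (su >= -half)
        & (su < half)
        & (sv >= -half)
        & (sv < half)
    )
    indices = np.full((len(pts), 2), -1, dtype=np.int64)
    indices[ok, 0] = iu[ok].astype(np.int64)
    indices[ok, 1] = iv[ok].astype(np.int64)
    return indices, coords
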