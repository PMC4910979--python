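"""Nearest-neighbour packing, radial distributions, annular-shell analysis.

Two packing measures summarise lipid crowding on a vesicle: MNND, the mean
over lipids of the 3D Euclidean distance to the nearest other lipid COM, and
MNNGC, the same statistic under the great-circle metric on the reference
sphere. MNNGC is the curved-surface analogue of the in-plane nearest
neighbour distance of flat bilayers and grows on smaller vesicles for the
same angular packing.

Lipids are partitioned into an annular shell (< 2 nm great-circle distance
from the nearest protein surface, strict) and bulk; radial distributions of
selected beads around the bilayer mid-radius give per-leaflet peaks, their
separation (the bilayer thickness proxy) and per-leaflet spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import Trajectory, VesicleFrame
from .spherical_geometry import SphereFrameRef, weighted_center_and_radius

__all__ = [
    "NeighborStats",
    "RadialDistribution",
    "mnnd",
    "mnngc",
    "neighbor_stats",
    "radial_distribution",
    "classify_annular",
    "annular_fraction_by_species",
    "residence_times",
]

ANNULAR_CUTOFF = 2.0  # nm, great-circle distance from the protein surface
CONTACT_CUTOFF = 0.6  # nm, first-shell bead-bead contact


def _nearest_distances(points: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        raise ValueError("need at least 2 points for nearest-neighbour distances")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def mnnd(coms: np.ndarray | VesicleFrame) -> float:
    """Mean 3D nearest-neighbour distance between lipid COMs (nm). Exact."""
    if isinstance(coms, VesicleFrame):
        _, coms = coms.lipid_coms()
    return float(_nearest_distances(np.asarray(coms, dtype=float)).mean())


def mnngc(coms: np.ndarray | VesicleFrame, ref: SphereFrameRef | None = None) -> float:
    """Mean great-circle nearest-neighbour distance between lipid COMs (nm).

    COMs are radially projected onto the reference sphere; nearest neighbours
    under the arc metric coincide with nearest neighbours under the chord
    metric on the projected points (the arc is monotone in the chord), so the
    query is exact.
    """
    if isinstance(coms, VesicleFrame):
        frame = coms
        _, coms = frame.lipid_coms()
        if ref is None:
            ref = weighted_center_and_radius(frame)
    if ref is None:
        raise ValueError("mnngc requires a SphereFrameRef for bare COM arrays")
    return float(_nn_arcs(np.asarray(coms, dtype=float), ref).mean())


def _nn_arcs(coms: np.ndarray, ref: SphereFrameRef) -> np.ndarray:
    units = ref.unit(coms)
    chord = _nearest_distances(units)
    return ref.mean_radius * 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


@dataclass
class NeighborStats:
    """Trajectory-level MNND/MNNGC: mean +/- SD over the per-frame series."""

    mnnd_mean: float
    mnnd_sd: float
    mnngc_mean: float
    mnngc_sd: float
    mnnd_series: np.ndarray
    mnngc_series: np.ndarray
    times: np.ndarray


def neighbor_stats(
    traj: Trajectory,
    exclude_annular: bool = False,
    annular_cutoff: float = ANNULAR_CUTOFF,
    per_leaflet_mnngc: bool = True,
) -> NeighborStats:
    """Per-frame MNND/MNNGC series and their trajectory mean +/- SD.

    With ``exclude_annular`` the annular shell around proteins is removed
    from the COM set first (the bulk-lipid variant). The reference sphere is
    recomputed per frame.

    MNND is the 3D statistic over all lipids. MNNGC is computed within each
    leaflet (per-lipid nearest-neighbour arcs pooled over both): projecting
    both leaflets onto one sphere would let a lipid's angular near-
    coincidence with its trans-leaflet partner dominate, collapsing the
    statistic below the in-plane spacing. ``per_leaflet_mnngc=False``
    restores the naive both-leaflet projection.
    """
    from .surface_maps import assign_leaflets

    mnnd_vals, mnngc_vals = [], []
    for frame in traj:
        ids, coms = frame.lipid_coms()
        ref = weighted_center_and_radius(frame)
        if exclude_annular:
            annular = classify_annular(frame, ref=ref, cutoff=annular_cutoff)
            keep = ~np.asarray([annular[i] for i in ids], dtype=bool)
            ids, coms = ids[keep], coms[keep]
        mnnd_vals.append(mnnd(coms))
        if per_leaflet_mnngc:
            leaflets = assign_leaflets(frame, ref)
            sides = np.asarray([leaflets.get(int(i), "outer") for i in ids])
            arcs = []
            for side in ("outer", "inner"):
                subset = coms[sides == side]
                if len(subset) >= 2:
                    arcs.append(_nn_arcs(subset, ref))
            mnngc_vals.append(float(np.concatenate(arcs).mean()))
        else:
            mnngc_vals.append(mnngc(coms, ref))
    mnnd_arr = np.asarray(mnnd_vals)
    mnngc_arr = np.asarray(mnngc_vals)
    sd = lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0  # noqa: E731
    return NeighborStats(
        mnnd_mean=float(mnnd_arr.mean()),
        mnnd_sd=sd(mnnd_arr),
        mnngc_mean=float(mnngc_arr.mean()),
        mnngc_sd=sd(mnngc_arr),
        mnnd_series=mnnd_arr,
        mnngc_series=mnngc_arr,
        times=traj.times,
    )


@dataclass
class RadialDistribution:
    """Histogram of signed radial positions about the bilayer mid-radius.

    The coordinate is r_bead - mean_radius (nm): negative for the inner
    leaflet, positive for the outer. ``sd`` is the pooled per-leaflet SD (the
    spread of each leaflet about its own mean, pooled), which is the leaflet
    broadening measure; the raw two-shell SD would be dominated by the
    bilayer half-thickness itself. ``peak_to_peak`` is NaN (with
    ``unimodal=True``) when no two distinct leaflet peaks exist.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    peak_inner: float
    peak_outer: float
    sd: float
    peak_to_peak: float
    mean_abs_distance: float
    unimodal: bool = False


def radial_distribution(
    frames: Trajectory | VesicleFrame | list[VesicleFrame],
    selection: np.ndarray | str | None = "headgroup",
    ref: SphereFrameRef | None = None,
    bin_width: float = 0.05,
) -> RadialDistribution:
    """Radial distribution of selected beads about the bilayer mid-radius.

    ``selection``: "headgroup" (default, the phosphate layer), "lipids", or a
    boolean mask. The reference sphere is recomputed per frame unless given.
    """
    if isinstance(frames, VesicleFrame):
        frames = [frames]
    radial: list[np.ndarray] = []
    for frame in frames:
        if isinstance(selection, str):
            mask = frame.headgroup_mask if selection == "headgroup" else frame.lipid_mask
        elif selection is None:
            mask = frame.lipid_mask
        else:
            mask = np.asarray(selection, dtype=bool)
        if not mask.any():
            raise ValueError("selection is empty")
        fref = ref if ref is not None else weighted_center_and_radius(frame)
        r = np.linalg.norm(frame.positions[mask] - fref.center, axis=1)
        radial.append(r - fref.mean_radius)
    x = np.concatenate(radial)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    inner = x < 0
    outer = ~inner
    unimodal = not (inner.any() and outer.any())
    if unimodal:
        warnings.warn("radial distribution is one-sided; peak-to-peak undefined", stacklevel=2)
        peak = centers[np.argmax(counts)]
        peak_inner = peak_outer = float(peak)
        peak_to_peak = float("nan")
        sd = float(x.std(ddof=0))
    else:
        in_bins = centers < 0
        peak_inner = float(centers[in_bins][np.argmax(counts[in_bins])])
        peak_outer = float(centers[~in_bins][np.argmax(counts[~in_bins])])
        peak_to_peak = peak_outer - peak_inner
        # pooled per-leaflet spread
        var = (
            np.sum((x[inner] - x[inner].mean()) ** 2)
            + np.sum((x[outer] - x[outer].mean()) ** 2)
        ) / len(x)
        sd = float(np.sqrt(var))
    return RadialDistribution(
        bin_edges=edges,
        counts=counts,
        peak_inner=peak_inner,
        peak_outer=peak_outer,
        sd=sd,
        peak_to_peak=peak_to_peak,
        mean_abs_distance=float(np.abs(x).mean()),
        unimodal=unimodal,
    )


def _protein_surface_arcs(
    frame: VesicleFrame, coms: np.ndarray, ref: SphereFrameRef
) -> np.ndarray:
    """Great-circle distance from each COM to the nearest protein bead.

    Protein beads are radially projected onto the reference sphere; the
    distance to "the protein surface" is the minimum arc to any of them.
    """
    prot = frame.positions[frame.protein_mask]
    pu = ref.unit(prot)
    cu = ref.unit(coms)
    cosang = np.clip(cu @ pu.T, -1.0, 1.0)
    return ref.mean_radius * np.arccos(cosang.max(axis=1))


def classify_annular(
    frame: VesicleFrame,
    ref: SphereFrameRef | None = None,
    cutoff: float = ANNULAR_CUTOFF,
) -> dict[int, bool]:
    """Label each lipid molecule annular (True) or bulk (False).

    A lipid is annular iff the great-circle distance from its COM to the
    nearest protein bead's radial projection is strictly below ``cutoff``
    (a lipid at exactly the cutoff is bulk). Without proteins everything is
    bulk, with a warning.
    """
    ids, coms = frame.lipid_coms()
    if ref is None:
        ref = weighted_center_and_radius(frame)
    if not frame.protein_mask.any():
        warnings.warn("no protein beads in frame; all lipids labelled bulk", stacklevel=2)
        return {int(i): False for i in ids}
    arcs = _protein_surface_arcs(frame, coms, ref)
    # strict < cutoff, with a 1e-9 nm guard so a lipid constructed exactly at
    # the boundary lands on the bulk side despite arccos rounding
    return {int(i): bool(a < cutoff - 1e-9) for i, a in zip(ids, arcs)}


def annular_fraction_by_species(
    traj: Trajectory | list[VesicleFrame], cutoff: float = ANNULAR_CUTOFF
) -> pd.DataFrame:
    """Per-frame fraction of all lipids that are annular, split by species.

    Rows: (time, species, fraction, n_annular, n_lipids). The per-species
    fractions of one frame sum to that frame's total annular fraction.
    """
    rows = []
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    for frame in frames:
        species_of = frame.lipid_species_table()
        n_lipids = len(species_of)
        if not frame.protein_mask.any():
            labels = {i: False for i in species_of}
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = classify_annular(frame, cutoff=cutoff)
        for sp in sorted({s for s in species_of.values()}):
            n_ann = sum(1 for i, s in species_of.items() if s == sp and labels[i])
            rows.append(
                {
                    "time": frame.time,
                    "species": sp,
                    "fraction": n_ann / n_lipids,
                    "n_annular": n_ann,
                    "n_lipids": n_lipids,
                }
            )
    return pd.DataFrame(rows)


def residence_times(
    traj: Trajectory, cutoff: float = CONTACT_CUTOFF
) -> pd.DataFrame:
    """Lipid-protein contact episode lifetimes (ns) per lipid species.

    A contact episode is a maximal run of consecutive frames in which the
    minimum 3D distance from any bead of the lipid to any protein bead is
    below ``cutoff``; its lifetime is (run length) * dt. Returns one row per
    episode: (molecule_id, species, start_time, lifetime).
    """
    frames = traj.frames
    species_of = frames[0].lipid_species_table()
    lipid_ids = sorted(species_of)
    contact = np.zeros((len(frames), len(lipid_ids)), dtype=bool)
    id_index = {mid: j for j, mid in enumerate(lipid_ids)}
    for k, frame in enumerate(frames):
        pmask = frame.protein_mask
        if not pmask.any():
            continue
        tree = cKDTree(frame.positions[pmask])
        lmask = frame.lipid_mask
        d, _ = tree.query(frame.positions[lmask])
        mols = frame.molecule_ids[lmask]
        close = d < cutoff
        for mid in np.unique(mols[close]):
            contact[k, id_index[int(mid)]] = True
    rows = []
    for j, mid in enumerate(lipid_ids):
        col = contact[:, j]
        k = 0
        while k < len(col):
            if col[k]:
                start = k
                while k < len(col) and col[k]:
                    k += 1
                rows.append(
                    {
                        "molecule_id": mid,
                        "species": species_of[mid],
                        "start_time": frames[start].time,
                        "lifetime": (k - start) * traj.dt,
                    }
                )
            else:
                k += 1
    return pd.DataFrame(rows, columns=["molecule_id", "species", "start_time", "lifetime"])
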