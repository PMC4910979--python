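"""Direction correlation of lipid and protein displacements on the sphere.

Over a time jump dt, a molecule's COM traces a great-circle arc whose unit
rotation axis is the normalised cross product of its centre-relative
positions at t and t + dt. Two molecules moving the same way share an axis
(cos theta = +1); opposite travel flips the axis (cos theta = -1). The
profile of mean cos theta versus great-circle distance from the protein
surface, per lipid species and per time jump, measures how far protein
motion drags the surrounding lipids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import Topology, Trajectory
from .spherical_geometry import weighted_center_and_radius

__all__ = [
    "DisplacementAxes",
    "CorrelationProfile",
    "displacement_axes",
    "correlation_profile",
    "fit_decay_length",
]

#: arcs smaller than this (radians) count as zero displacement and are flagged
MIN_STEP_SIN = 1e-12


@dataclass
class DisplacementAxes:
    """Unit rotation axes of COM great-circle steps.

    ``axes[t, j]`` is the axis of molecule j's step starting at frame index
    ``start_frames[t]``; NaN rows mark flagged zero-displacement steps
    (excluded from averages downstream).
    """

    molecule_ids: np.ndarray  # (n_mols,)
    start_frames: np.ndarray  # (n_steps,)
    axes: np.ndarray  # (n_steps, n_mols, 3)
    dt_jump: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.axes[..., 0])


def _com_series(traj: Trajectory, which: str, topology: Topology | None) -> tuple[np.ndarray, np.ndarray]:
    """(molecule ids, (n_frames, n_mols, 3) centre-relative COM series)."""
    series = []
    ids = None
    for frame in traj:
        ref = weighted_center_and_radius(frame)
        if which == "lipids":
            fids, coms = frame.lipid_coms()
        elif which == "proteins":
            if topology is None or not topology.trimers:
                raise ValueError("protein axes require a topology with a trimer roster")
            fids = np.asarray(sorted(topology.trimers))
            coms = np.stack(
                [
                    frame.positions[np.isin(frame.molecule_ids, list(topology.trimers[t]))].mean(axis=0)
                    for t in fids
                ]
            )
        else:
            raise ValueError(f"unknown selection {which!r}")
        if ids is None:
            ids = fids
        series.append(coms - ref.center)
    return ids, np.stack(series)


def displacement_axes(
    traj: Trajectory,
    dt_jump: float,
    which: str = "lipids",
    topology: Topology | None = None,
) -> DisplacementAxes:
    """Rotation axes of every molecule's great-circle step of length dt_jump.

    ``dt_jump`` must be a multiple of the trajectory spacing. Steps with
    (numerically) zero angular displacement have no defined axis and come
    back as NaN.
    """
    ratio = dt_jump / traj.dt
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise ValueError(
            f"dt_jump {dt_jump} ns is not a positive multiple of trajectory dt {traj.dt} ns"
        )
    ids, coms = _com_series(traj, which, topology)
    a = coms[:-step]
    b = coms[step:]
    cross = np.cross(a, b)
    nc = np.linalg.norm(cross, axis=-1)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    sin_theta = nc / (na * nb)
    axes = np.full_like(cross, np.nan)
    ok = sin_theta > MIN_STEP_SIN
    axes[ok] = cross[ok] / nc[ok, None]
    return DisplacementAxes(
        molecule_ids=ids,
        start_frames=np.arange(len(a)),
        axes=axes,
        dt_jump=dt_jump,
    )


@dataclass
class CorrelationProfile:
    """Mean direction correlation vs distance from the protein surface.

    ``mean[s, b]`` is the average cos theta of species ``species[s]`` in
    distance bin b (NaN where ``counts`` is 0; empty bins are reported, not
    dropped). Distances are great-circle nm from the lipid COM to the
    protein surface (or COM, per ``distance_to``) at the start of the step.
    """

    dt_jump: float
    bin_edges: np.ndarray
    species: list[str]
    mean: np.ndarray  # (n_species, n_bins)
    counts: np.ndarray  # (n_species, n_bins)
    distance_to: str = "surface"

    def as_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        rows = []
        for s, sp in enumerate(self.species):
            for b, c in enumerate(centers):
                rows.append(
                    {
                        "dt_jump": self.dt_jump,
                        "species": sp,
                        "distance": c,
                        "mean_cos": self.mean[s, b],
                        "count": int(self.counts[s, b]),
                    }
                )
        return pd.DataFrame(rows)


def correlation_profile(
    traj: Trajectory,
    topology: Topology,
    dt_jump: float,
    bin_edges: np.ndarray | None = None,
    distance_to: str = "surface",
) -> CorrelationProfile:
    """Lipid-protein direction correlation binned by distance from protein.

    For every (lipid, protein, step) with both axes defined, the dot product
    of their rotation axes is accumulated into the distance bin of the lipid
    at the step start, relative to that same protein. Bins default to
    0.25 nm out to 15 nm. Means are reported per lipid species.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 15.0 + 0.25, 0.25)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if distance_to not in ("surface", "com"):
        raise ValueError("distance_to must be 'surface' or 'com'")

    lip = displacement_axes(traj, dt_jump, "lipids")
    prot = displacement_axes(traj, dt_jump, "proteins", topology)
    species_of = traj.frames[0].lipid_species_table()
    species = sorted(set(species_of.values()))
    sp_index = {sp: s for s, sp in enumerate(species)}
    lipid_species_idx = np.asarray([sp_index[species_of[int(i)]] for i in lip.molecule_ids])

    n_bins = len(bin_edges) - 1
    sums = np.zeros((len(species), n_bins))
    counts = np.zeros((len(species), n_bins), dtype=np.int64)
    trimer_ids = sorted(topology.trimers)

    for t in range(len(lip.start_frames)):
        frame = traj.frames[t]
        ref = weighted_center_and_radius(frame)
        ids, coms = frame.lipid_coms()
        lip_units = ref.unit(coms)
        for p, tid in enumerate(trimer_ids):
            p_axis = prot.axes[t, p]
            if not np.isfinite(p_axis[0]):
                continue
            rows = np.isin(frame.molecule_ids, list(topology.trimers[tid]))
            if distance_to == "surface":
                target_units = ref.unit(frame.positions[rows])
            else:
                target_units = ref.unit(frame.positions[rows].mean(axis=0))[None, :]
            cosang = np.clip(lip_units @ target_units.T, -1.0, 1.0)
            dist = ref.mean_radius * np.arccos(cosang.max(axis=1))
            cos = lip.axes[t] @ p_axis
            ok = np.isfinite(cos)
            which_bin = np.digitize(dist, bin_edges) - 1
            ok &= (which_bin >= 0) & (which_bin < n_bins)
            np.add.at(sums, (lipid_species_idx[ok], which_bin[ok]), cos[ok])
            np.add.at(counts, (lipid_species_idx[ok], which_bin[ok]), 1)

    mean = np.full_like(sums, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return CorrelationProfile(
        dt_jump=dt_jump,
        bin_edges=bin_edges,
        species=species,
        mean=mean,
        counts=counts,
        distance_to=distance_to,
    )


def fit_decay_length(
    profile: CorrelationProfile,
    d_min: float,
    d_max: float,
    min_count: int = 50,
) -> float:
    """Exponential decay length (nm) of the pooled correlation profile.

    Pools all species, then fits log(mean cos) linearly against bin-centre
    distance over [d_min, d_max], using bins with positive mean and at least
    ``min_count`` samples. Returns NaN when fewer than 3 bins qualify.
    """
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    total = profile.counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pooled = np.nansum(
            np.where(np.isfinite(profile.mean), profile.mean, 0.0) * profile.counts, axis=0
        ) / np.maximum(total, 1)
    ok = (
        (centers >= d_min)
        & (centers <= d_max)
        & (total >= min_count)
        & (pooled > 0)
    )
    if ok.sum() < 3:
        return float("nan")
    slope, _ = np.polyfit(centers[ok], np.log(pooled[ok]), 1)
    if slope >= 0:
        return float("inf")
    return -1.0 / slope
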