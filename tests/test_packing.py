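"""Packing statistics against brute-force oracles and planted partitions."""

import numpy as np
import pytest

from vesisphere.model_io import Trajectory
from vesisphere.packing_stats import (
    annular_fraction_by_species,
    classify_annular,
    mnnd,
    mnngc,
    neighbor_stats,
    radial_distribution,
    residence_times,
)
from vesisphere.spherical_geometry import SphereFrameRef
from vesisphere.vesicle_builder import fibonacci_sphere

from conftest import concentric_shell_frame, two_bead_lipid_frame, make_trajectory


def brute_force_mnnd(points):
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1).mean()


def brute_force_mnngc(points, ref):
    u = (points - ref.center) / np.linalg.norm(points - ref.center, axis=1, keepdims=True)
    ang = np.arccos(np.clip(u @ u.T, -1, 1))
    np.fill_diagonal(ang, np.inf)
    return ref.mean_radius * ang.min(axis=1).mean()


class TestNearestNeighbour:
    def test_tetrahedron_closed_form(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        assert mnnd(tet) == pytest.approx(np.sqrt(8 / 3), rel=1e-12)

    def test_two_points(self):
        assert mnnd(np.array([[0.0, 0, 0], [0.0, 0, 3.5]])) == pytest.approx(3.5)

    def test_antipodal_great_circle(self):
        ref = SphereFrameRef(np.zeros(3), 8.4)
        pts = np.array([[8.4, 0, 0], [-8.4, 0, 0]])
        assert mnngc(pts, ref) == pytest.approx(np.pi * 8.4, rel=1e-12)

    def test_matches_brute_force_oracles(self, rng):
        u = rng.standard_normal((500, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = 12.0 * u + 0.2 * rng.standard_normal((500, 3))
        ref = SphereFrameRef(np.zeros(3), 12.0)
        assert mnnd(pts) == pytest.approx(brute_force_mnnd(pts), rel=1e-12)
        assert mnngc(pts, ref) == pytest.approx(brute_force_mnngc(pts, ref), rel=1e-12)

    def test_mnngc_scales_linearly_with_radius(self):
        u = fibonacci_sphere(300)
        for scale in (2.0, 5.0):
            r1 = SphereFrameRef(np.zeros(3), 10.0)
            r2 = SphereFrameRef(np.zeros(3), 10.0 * scale)
            assert mnngc(u * 10.0 * scale, r2) == pytest.approx(
                scale * mnngc(u * 10.0, r1), rel=1e-9
            )

    def test_same_chord_spacing_larger_arc_on_smaller_sphere(self):
        # fix the chordal nearest-neighbour spacing; curvature makes the
        # great-circle distance longer on the smaller vesicle
        chord = 0.6
        arcs = []
        for R in (8.4, 32.8):
            ang = 2 * np.arcsin(chord / (2 * R))
            pts = R * np.array(
                [[1, 0, 0], [np.cos(ang), np.sin(ang), 0.0]]
            )
            arcs.append(mnngc(pts, SphereFrameRef(np.zeros(3), R)))
        assert arcs[0] > arcs[1]
        assert arcs[1] == pytest.approx(chord, rel=1e-3)

    def test_fewer_than_two_lipids_raises(self):
        with pytest.raises(ValueError):
            mnnd(np.array([[0.0, 0, 0]]))


class TestRadialDistribution:
    def test_delta_shells_give_bulk_thickness(self):
        frame = concentric_shell_frame(n_per_leaflet=400, r_inner=30.7, r_outer=35.0)
        ref = SphereFrameRef(np.zeros(3), 32.85)
        dist = radial_distribution(frame, ref=ref, bin_width=0.05)
        assert dist.peak_to_peak == pytest.approx(4.3, abs=0.05)
        assert not dist.unimodal

    def test_gaussian_shell_sd_recovered(self, rng):
        frame = concentric_shell_frame(n_per_leaflet=5000, noise=0.33, rng=rng)
        ref = SphereFrameRef(np.zeros(3), 32.85)
        dist = radial_distribution(frame, ref=ref)
        assert dist.sd == pytest.approx(0.33, abs=0.02)

    def test_single_shell_flagged_unimodal(self):
        u = fibonacci_sphere(300)
        frame = two_bead_lipid_frame(np.full(300, 21.0), u, np.ones(300))
        ref = SphereFrameRef(np.zeros(3), 20.0)
        with pytest.warns(UserWarning, match="one-sided"):
            dist = radial_distribution(frame, ref=ref)
        assert np.isnan(dist.peak_to_peak)
        assert dist.peak_inner == dist.peak_outer


class TestAnnularClassification:
    def make_frame_with_protein(self, arc_distances, R=20.0):
        # lipids at controlled great-circle distances from a single protein
        # bead placed at the north pole (radially projected)
        angles = np.asarray(arc_distances) / R
        units = np.column_stack(
            [np.sin(angles), np.zeros(len(angles)), np.cos(angles)]
        )
        prot = np.array([[0.0, 0.0, R]])
        return two_bead_lipid_frame(
            np.full(len(angles), R), units, np.ones(len(angles)), extra_positions=prot
        )

    def test_strict_boundary_convention(self):
        frame = self.make_frame_with_protein([1.0, 2.0, 3.0])
        ref = SphereFrameRef(np.zeros(3), 20.0)
        labels = classify_annular(frame, ref=ref, cutoff=2.0)
        assert labels[0] is True  # 1 nm: annular
        assert labels[1] is False  # exactly 2 nm: bulk (strict <)
        assert labels[2] is False

    def test_planted_shell_recovered_exactly(self, rng):
        n = 400
        arcs = np.concatenate([rng.uniform(0.2, 1.9, 120), rng.uniform(2.2, 15.0, n - 120)])
        frame = self.make_frame_with_protein(arcs)
        ref = SphereFrameRef(np.zeros(3), 20.0)
        labels = classify_annular(frame, ref=ref, cutoff=2.0)
        assert sum(labels.values()) == 120
        assert all(labels[i] == (arcs[i] < 2.0) for i in range(n))

    def test_no_proteins_warns_all_bulk(self):
        u = fibonacci_sphere(50)
        frame = two_bead_lipid_frame(np.full(50, 20.0), u, np.ones(50))
        with pytest.warns(UserWarning, match="no protein"):
            labels = classify_annular(frame)
        assert not any(labels.values())

    def test_partition_exhaustive_and_exclusive(self):
        frame = self.make_frame_with_protein(np.linspace(0.3, 12, 100))
        labels = classify_annular(frame, ref=SphereFrameRef(np.zeros(3), 20.0))
        assert set(labels) == set(range(100))


class TestAnnularFractions:
    def test_planted_species_fractions(self, rng):
        # 16% of lipids are annular species A, 11% annular species B
        n = 200
        arcs = np.full(n, 10.0)
        annular_idx = rng.permutation(n)[:54]
        arcs[annular_idx] = rng.uniform(0.3, 1.9, 54)
        species = np.array(["DSPC"] * n, dtype=object)
        species[annular_idx[:32]] = "DLPC"  # 32/200 = 16% annular DLPC
        species[annular_idx[32:]] = "DSPC"  # 22/200 = 11% annular DSPC
        bulk = np.setdiff1d(np.arange(n), annular_idx)
        species[bulk[: len(bulk) // 2]] = "DLPC"
        R = 20.0
        angles = arcs / R
        units = np.column_stack([np.sin(angles), np.zeros(n), np.cos(angles)])
        frame = two_bead_lipid_frame(
            np.full(n, R), units, np.ones(n), species=list(species),
            extra_positions=np.array([[0.0, 0.0, R]]),
        )
        table = annular_fraction_by_species(make_trajectory([frame]), cutoff=2.0)
        by_sp = dict(zip(table["species"], table["fraction"]))
        assert by_sp["DLPC"] == pytest.approx(0.16)
        assert by_sp["DSPC"] == pytest.approx(0.11)
        assert sum(by_sp.values()) == pytest.approx(54 / 200)

    def test_no_proteins_gives_zero(self):
        u = fibonacci_sphere(40)
        frame = two_bead_lipid_frame(np.full(40, 20.0), u, np.ones(40))
        table = annular_fraction_by_species(make_trajectory([frame]))
        assert (table["fraction"] == 0).all()

    def test_all_within_cutoff_sums_to_one(self):
        R = 30.0
        angles = np.linspace(0.005, 0.05, 30)
        units = np.column_stack([np.sin(angles), np.zeros(30), np.cos(angles)])
        frame = two_bead_lipid_frame(
            np.full(30, R), units, np.ones(30),
            species=["DSPC"] * 15 + ["DLPC"] * 15,
            extra_positions=np.array([[0.0, 0.0, R]]),
        )
        table = annular_fraction_by_species(make_trajectory([frame]), cutoff=2.0)
        assert table["fraction"].sum() == pytest.approx(1.0)


class TestResidenceTimes:
    @staticmethod
    def traj_from_contact_schedule(schedule: np.ndarray, dt=2.0):
        """Frames where lipid i touches the protein iff schedule[frame, i]."""
        n_frames, n_lip = schedule.shape
        R = 20.0
        prot = np.array([[0.0, 0.0, R]])
        frames = []
        base_angles = np.linspace(0.5, 1.2, n_lip)  # far: > cutoff
        for k in range(n_frames):
            ang = np.where(schedule[k], 0.02, base_angles)
            units = np.column_stack([np.sin(ang), np.zeros(n_lip), np.cos(ang)])
            frames.append(
                two_bead_lipid_frame(np.full(n_lip, R), units, np.ones(n_lip),
                                     extra_positions=prot, time=k * dt)
            )
        return Trajectory(frames=frames, dt=dt)

    def test_single_episode_lifetime(self):
        schedule = np.zeros((20, 1), dtype=bool)
        schedule[0:10, 0] = True
        table = residence_times(self.traj_from_contact_schedule(schedule), cutoff=0.6)
        assert len(table) == 1
        assert table["lifetime"].iloc[0] == pytest.approx(20.0)  # 10 frames x 2 ns

    def test_never_in_contact_empty(self):
        schedule = np.zeros((10, 3), dtype=bool)
        table = residence_times(self.traj_from_contact_schedule(schedule), cutoff=0.6)
        assert table.empty

    def test_exponential_dwell_mean_recovered(self, rng):
        # ~500 episodes with geometric (discretised exponential) dwell times
        # of mean 25 frames = 50 ns
        n_lip, n_frames, dt = 25, 1600, 2.0
        p_leave, p_enter = 1 / 25, 1 / 15
        schedule = np.zeros((n_frames, n_lip), dtype=bool)
        state = rng.random(n_lip) < 0.5
        for k in range(n_frames):
            schedule[k] = state
            leave = rng.random(n_lip) < p_leave
            enter = rng.random(n_lip) < p_enter
            state = np.where(state, ~leave, enter)
        table = residence_times(self.traj_from_contact_schedule(schedule, dt), cutoff=0.6)
        # drop censored first/last episodes per lipid
        interior = table[(table["start_time"] > 0)
                         & (table["start_time"] + table["lifetime"] < n_frames * dt)]
        assert len(interior) > 400
        assert interior["lifetime"].mean() == pytest.approx(25 * dt, rel=0.15)


def test_removing_denser_annular_shell_increases_mnnd():
    # plant a dense annular ring around the protein and sparse bulk
    R = 20.0
    rng = np.random.default_rng(5)
    n_ann, n_bulk = 150, 350
    ann_ang = np.column_stack([rng.uniform(0.02, 1.8 / R, n_ann),
                               rng.uniform(0, 2 * np.pi, n_ann)])
    bulk_ang = np.column_stack([np.arccos(rng.uniform(-1, 0.9, n_bulk)),
                                rng.uniform(0, 2 * np.pi, n_bulk)])
    ang = np.vstack([ann_ang, bulk_ang])
    units = np.column_stack([
        np.sin(ang[:, 0]) * np.cos(ang[:, 1]),
        np.sin(ang[:, 0]) * np.sin(ang[:, 1]),
        np.cos(ang[:, 0]),
    ])
    frame = two_bead_lipid_frame(
        np.full(len(units), R), units, np.ones(len(units)),
        extra_positions=np.array([[0.0, 0.0, R]]),
    )
    traj = make_trajectory([frame])
    with_annular = neighbor_stats(traj)
    bulk_only = neighbor_stats(traj, exclude_annular=True)
    assert bulk_only.mnnd_mean > with_annular.mnnd_mean
    assert bulk_only.mnngc_mean > with_annular.mnngc_mean
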