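"""Rigid-motion removal and protein-centred height/thickness/occupancy maps."""

import numpy as np
import pytest

from vesisphere.model_io import Trajectory, VesicleFrame
from vesisphere.spherical_geometry import SphereFrameRef
from vesisphere.surface_maps import (
    assign_leaflets,
    leaflet_height_map,
    occupancy_map,
    protein_grid,
    remove_protein_motion,
    thickness_map,
)
from vesisphere.synthetic_trajectory import DynamicsSpec, simulate
from vesisphere.vesicle_builder import BuildSpec

from conftest import concentric_shell_frame, make_trajectory


@pytest.fixture(scope="module")
def protein_vesicle():
    spec = DynamicsSpec(
        build=BuildSpec(radius=12.0, n_proteins=1, area_per_lipid=1.5, seed=3,
                        species_mix=[("DSPC", 0.5), ("DLPC", 0.5)]),
        n_frames=4, dt=2.0, lipid_diffusion=0.01, protein_rot_diffusion=5e-4, seed=4,
    )
    return simulate(spec)


def rotate_frame(frame: VesicleFrame, rotation: np.ndarray, center: np.ndarray, time: float):
    return VesicleFrame(
        positions=(frame.positions - center) @ rotation.T + center,
        molecule_ids=frame.molecule_ids,
        species=frame.species,
        roles=frame.roles,
        bead_names=frame.bead_names,
        time=time,
    )


def rotmat(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


class TestRemoveProteinMotion:
    def test_planted_transport_and_spin_inverted_exactly(self, protein_vesicle):
        res = protein_vesicle
        f0 = res.trajectory.frames[0]
        center = f0.positions[f0.lipid_mask].mean(axis=0)
        rows = np.isin(f0.molecule_ids, list(res.topology.trimers[0]))
        u0 = f0.positions[rows].mean(axis=0) - center
        u0 /= np.linalg.norm(u0)
        transport = rotmat(np.cross(u0, [0.0, 0.0, 1.0]), 1.0)
        spin = rotmat(transport @ u0, 0.5)
        f1 = rotate_frame(f0, spin @ transport, center, time=2.0)
        aligned, transforms = remove_protein_motion(
            Trajectory(frames=[f0, f1], dt=2.0), res.topology, 0
        )
        np.testing.assert_allclose(
            aligned.frames[1].positions[rows], f0.positions[rows], atol=1e-9
        )

    def test_identity_motion_gives_identity_transform(self, protein_vesicle):
        res = protein_vesicle
        f0 = res.trajectory.frames[0]
        f1 = rotate_frame(f0, np.eye(3), np.zeros(3), time=2.0)
        aligned, transforms = remove_protein_motion(
            Trajectory(frames=[f0, f1], dt=2.0), res.topology, 0
        )
        np.testing.assert_allclose(transforms[1].rotation, np.eye(3), atol=1e-9)

    def test_internal_vibration_survives_alignment(self, protein_vesicle, rng):
        # rigid transport + small internal jitter: post-alignment RMSD of the
        # protein equals the jitter level, not the transport
        res = protein_vesicle
        f0 = res.trajectory.frames[0]
        center = f0.positions[f0.lipid_mask].mean(axis=0)
        rows = np.isin(f0.molecule_ids, list(res.topology.trimers[0]))
        sigma = 0.05
        transport = rotmat([0.0, 1.0, 0.0], 0.8)
        f1 = rotate_frame(f0, transport, center, time=2.0)
        f1.positions[rows] += sigma * rng.standard_normal((rows.sum(), 3))
        aligned, _ = remove_protein_motion(
            Trajectory(frames=[f0, f1], dt=2.0), res.topology, 0
        )
        rmsd = np.sqrt(
            np.mean(np.sum((aligned.frames[1].positions[rows] - f0.positions[rows]) ** 2, axis=1))
        )
        assert rmsd == pytest.approx(np.sqrt(3) * sigma, rel=0.35)
        assert rmsd < 0.2  # far below the ~9 nm transport displacement


def shell_trajectory(n_frames=3, **kw):
    prot = np.array([[0.0, 0.3, 32.8], [0.3, 0.0, 32.8], [0.0, -0.3, 32.8]])
    frames = [
        concentric_shell_frame(n_per_leaflet=2500, extra_positions=prot, **kw)
        for _ in range(n_frames)
    ]
    return make_trajectory(frames)


def shell_topology():
    from vesisphere.model_io import Topology, Role

    top = Topology()
    top.protein_species.add("OMPF")
    top.bead_roles[("OMPF", "BB*")] = Role.PROTEIN_BACKBONE
    top.trimers[0] = (2 * 2500, 2 * 2500 + 1, 2 * 2500 + 2)
    return top


class TestHeightAndThickness:
    def test_concentric_shells_give_uniform_maps(self):
        traj = shell_trajectory()
        top = shell_topology()
        aligned, _ = remove_protein_motion(traj, top, 0)
        grid = protein_grid(aligned, top, 0, cell_edge=0.5, n_cells=16)
        inner = leaflet_height_map(aligned, grid, "inner")
        outer = leaflet_height_map(aligned, grid, "outer")
        thick = thickness_map(inner, outer)
        # exact up to the per-frame centre estimate (~1e-5 nm here)
        assert np.nanmax(np.abs(inner.values - 30.7)) < 1e-4
        assert np.nanmax(np.abs(outer.values - 35.0)) < 1e-4
        assert np.nanmax(np.abs(thick.values - 4.3)) < 1e-4

    def test_inner_dimple_increases_thickness(self):
        # a dip of the inner leaflet only (toward the centre) must show up as
        # *increased* thickness where it dips — the sign convention check
        def dimple(units):
            ang = np.arccos(np.clip(units[:, 2], -1, 1))
            return -0.5 * np.exp(-((32.85 * ang) ** 2) / (2 * 3.0**2))

        n = 6000
        prot = np.array([[0.0, 0.3, 32.8], [0.3, 0.0, 32.8], [0.0, -0.3, 32.8]])
        frames = [
            concentric_shell_frame(n_per_leaflet=n, extra_positions=prot,
                                   bump_inner=dimple)
            for _ in range(2)
        ]
        traj = make_trajectory(frames)
        top = shell_topology_n(n)
        grid = protein_grid(traj, top, 0, cell_edge=1.0, n_cells=10)
        inner = leaflet_height_map(traj, grid, "inner")
        outer = leaflet_height_map(traj, grid, "outer")
        thick = thickness_map(inner, outer)
        centre = thick.values[5, 5]
        corners = np.nanmean(
            [thick.values[0, 0], thick.values[0, 9], thick.values[9, 9]]
        )
        assert centre > corners + 0.3
        assert centre == pytest.approx(4.3 + 0.5, abs=0.1)

    def test_thickness_identity_and_grid_mismatch(self):
        traj = shell_trajectory(n_frames=2)
        top = shell_topology()
        grid = protein_grid(traj, top, 0, cell_edge=0.5, n_cells=10)
        inner = leaflet_height_map(traj, grid, "inner")
        outer = leaflet_height_map(traj, grid, "outer")
        thick = thickness_map(inner, outer)
        ok = np.isfinite(thick.values)
        np.testing.assert_allclose(
            (thick.values + inner.values)[ok], outer.values[ok], atol=1e-12
        )
        other = protein_grid(traj, top, 0, cell_edge=0.4, n_cells=10)
        inner2 = leaflet_height_map(traj, other, "inner")
        with pytest.raises(ValueError, match="same grid"):
            thickness_map(inner2, outer)

    def test_planted_dimple_depth_recovered(self, rng):
        # 0.5 nm Gaussian thinning dimple + radial noise, 200 frames
        prot = np.array([[0.0, 0.3, 32.8], [0.3, 0.0, 32.8], [0.0, -0.3, 32.8]])

        def dimple(units):
            ang = np.arccos(np.clip(units[:, 2], -1, 1))
            return -0.5 * np.exp(-((32.85 * ang) ** 2) / (2 * 2.0**2))

        from vesisphere.vesicle_builder import fibonacci_sphere

        n = 4000
        lattice = fibonacci_sphere(n)
        frames = []
        for _ in range(200):
            q, _r = np.linalg.qr(rng.standard_normal((3, 3)))
            frames.append(
                concentric_shell_frame(
                    n_per_leaflet=n, extra_positions=prot, noise=0.15, rng=rng,
                    radial_bump=dimple, units=lattice @ q.T,
                )
            )
        traj = make_trajectory(frames)
        top = shell_topology_n(n)
        grid = protein_grid(traj, top, 0, cell_edge=1.0, n_cells=11)
        outer = leaflet_height_map(traj, grid, "outer")
        coords = grid.edge_coordinates()
        uu, vv = np.meshgrid(coords, coords, indexing="ij")
        dist = np.hypot(uu, vv)
        centre = np.nanmean(outer.values[dist < 1.0])
        edge = np.nanmean(outer.values[dist > 4.5])
        planted_centre = dimple(np.array([[0.0, 0.0, 1.0]]))[0]
        assert centre - edge == pytest.approx(planted_centre, abs=0.05)


def shell_topology_n(n):
    from vesisphere.model_io import Topology, Role

    top = Topology()
    top.protein_species.add("OMPF")
    top.bead_roles[("OMPF", "BB*")] = Role.PROTEIN_BACKBONE
    top.trimers[0] = (2 * n, 2 * n + 1, 2 * n + 2)
    return top


class TestOccupancy:
    def test_fractions_sum_to_one_and_missing_is_nan(self, protein_vesicle):
        res = protein_vesicle
        aligned, _ = remove_protein_motion(res.trajectory, res.topology, 0)
        grid = protein_grid(aligned, res.topology, 0, cell_edge=0.5, n_cells=16)
        occ = occupancy_map(aligned, grid, ["DSPC", "DLPC"], leaflet="outer")
        total = occ["DSPC"].values + occ["DLPC"].values
        visited = np.isfinite(total)
        assert visited.any()
        np.testing.assert_allclose(total[visited], 1.0, atol=1e-12)
        missing = occ["DSPC"].counts + occ["DLPC"].counts == 0
        assert np.isnan(occ["DSPC"].values[missing]).all()

    def test_planted_species_ring_enriched(self, rng):
        # species A planted in a ring 2-6 nm from the protein
        R = 32.85
        n = 2000
        prot = np.array([[0.0, 0.3, R], [0.3, 0.0, R], [0.0, -0.3, R]])
        frame = concentric_shell_frame(n_per_leaflet=n, extra_positions=prot)
        units = frame.positions[frame.headgroup_mask][:n]
        units = units / np.linalg.norm(units, axis=1, keepdims=True)
        arc = R * np.arccos(np.clip(units[:, 2], -1, 1))
        species = np.where((arc > 2) & (arc < 6), "DSPC", "DLPC")
        # outer-leaflet lipids are the first n molecules
        sp = np.asarray(frame.species)
        for i in range(n):
            sp[2 * i] = sp[2 * i + 1] = species[i]
        frame.species = sp
        traj = make_trajectory([frame])
        grid = protein_grid(traj, shell_topology_n(n), 0, cell_edge=1.0, n_cells=12)
        occ = occupancy_map(traj, grid, ["DSPC", "DLPC"], leaflet="outer")
        coords = grid.edge_coordinates()
        uu, vv = np.meshgrid(coords, coords, indexing="ij")
        dist = np.hypot(uu, vv)
        ring = (dist > 2.5) & (dist < 5.5) & np.isfinite(occ["DSPC"].values)
        outside = (dist > 7.0) & np.isfinite(occ["DSPC"].values)
        assert np.nanmean(occ["DSPC"].values[ring]) > 0.9
        assert np.nanmean(occ["DSPC"].values[outside]) < 0.1

    def test_single_species_rejected(self, protein_vesicle):
        res = protein_vesicle
        grid = protein_grid(res.trajectory, res.topology, 0, cell_edge=0.5, n_cells=8)
        with pytest.raises(ValueError, match="2 species"):
            occupancy_map(res.trajectory, grid, ["DSPC"])


class TestLeafletAssignment:
    def test_shell_frame_leaflets(self):
        frame = concentric_shell_frame(n_per_leaflet=100)
        leaflets = assign_leaflets(frame, SphereFrameRef(np.zeros(3), 32.85))
        labels = list(leaflets.values())
        assert labels[:100] == ["outer"] * 100
        assert labels[100:] == ["inner"] * 100

    def test_height_map_invariant_under_global_rotation(self, protein_vesicle, rng):
        res = protein_vesicle
        q = rotmat(rng.standard_normal(3), 0.7)
        rotated = Trajectory(
            frames=[rotate_frame(f, q, np.zeros(3), f.time) for f in res.trajectory],
            dt=res.trajectory.dt,
        )
        for traj in (res.trajectory, rotated):
            aligned, _ = remove_protein_motion(traj, res.topology, 0)
        # maps from the two alignments agree cell-wise
        a1, _ = remove_protein_motion(res.trajectory, res.topology, 0)
        a2, _ = remove_protein_motion(rotated, res.topology, 0)
        g1 = protein_grid(a1, res.topology, 0, cell_edge=1.0, n_cells=8)
        g2 = protein_grid(a2, res.topology, 0, cell_edge=1.0, n_cells=8)
        m1 = leaflet_height_map(a1, g1, "outer")
        m2 = leaflet_height_map(a2, g2, "outer")
        both = np.isfinite(m1.values) & np.isfinite(m2.values)
        np.testing.assert_allclose(m1.values[both], m2.values[both], atol=1e-6)
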