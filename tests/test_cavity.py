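"""Voxel-grid cavity detection vs independent oracles and closed forms."""

import numpy as np
import pytest

import cavistat as cs
from cavistat.cavity import STATE_FREE, STATE_OUTSIDE, STATE_PROTEIN

from conftest import TRIAD, run_cavity
from oracles import bfs_components


def _classified_grid(traj, spacing=0.5, probe=0.0):
    prot = cs.select(traj, role="protein")
    coords = traj.coordinates(0)
    grid = cs.build_grid(coords, prot, spacing=spacing)
    cs.classify_voxels(grid, coords, prot, traj.radii, traj.heavy_mask, probe)
    return grid, prot, coords


class TestGridBuild:
    def test_dims_cover_bounding_box_plus_padding(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(50, 3))
        coords[:4] = [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]]
        grid = cs.build_grid(coords, np.arange(50), spacing=0.5, padding=2.0)
        assert grid.dims == (28, 28, 28)
        np.testing.assert_allclose(grid.origin, [-2, -2, -2])

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            cs.build_grid(np.zeros((4, 3)), np.arange(4), spacing=0.0)

    def test_degenerate_point_set_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="coplanar|degenerate"):
            cs.build_grid(flat, np.arange(4), spacing=0.5)


class TestClassification:
    def test_voxel_inside_vdw_radius_is_protein(self):
        # 1 Å from a C atom (r 1.70), probe 0 → protein
        coords = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8], [8, 8, 8]], float)
        grid = cs.build_grid(coords, np.arange(5), spacing=0.5, padding=2.0)
        radii = np.full(5, 1.70)
        cs.classify_voxels(grid, coords, np.arange(5), radii)
        flat = grid.voxel_index_of(np.array([[1.0, 0.0, 0.0]]))[0]
        assert grid.state.ravel()[flat] == STATE_PROTEIN

    def test_far_corner_is_outside_hull(self, box_pocket):
        traj, _ = box_pocket
        grid, _, _ = _classified_grid(traj)
        corner = grid.voxel_index_of(grid.origin + 0.3)[0]
        assert grid.state.ravel()[corner] == STATE_OUTSIDE

    def test_shell_interior_is_free_in_hull(self, box_pocket):
        traj, _ = box_pocket
        grid, _, _ = _classified_grid(traj)
        center = grid.voxel_index_of(np.array([[5.0, 5.0, 5.0]]))[0]
        assert grid.state.ravel()[center] == STATE_FREE

    def test_state_conservation(self, box_pocket):
        traj, _ = box_pocket
        grid, _, _ = _classified_grid(traj)
        counts = np.bincount(grid.state.ravel(), minlength=4)
        assert counts[STATE_PROTEIN] + counts[STATE_FREE] + counts[STATE_OUTSIDE] == grid.n_voxels


class TestComponents:
    def test_two_pockets_two_labels(self, gated_shells):
        _, _, closed_traj, gt_closed = gated_shells
        assert gt_closed.n_components == 2
        grid, _, _ = _classified_grid(closed_traj)
        cs.label_components(grid)
        interior = [
            int(grid.labels.ravel()[grid.voxel_index_of(np.array([p]))[0]])
            for p in ([3.0, 3.0, 3.0], [9.0, 3.0, 3.0])
        ]
        assert interior[0] > 0 and interior[1] > 0 and interior[0] != interior[1]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labels_match_bfs_oracle(self, box_pocket, connectivity):
        traj, _ = box_pocket
        grid, _, _ = _classified_grid(traj)
        cs.label_components(grid, connectivity)
        oracle = bfs_components(grid.state == STATE_FREE, connectivity)
        assert np.array_equal(grid.labels, oracle)

    def test_single_pocket_same_label_all_connectivities(self, box_pocket):
        traj, _ = box_pocket
        pocket_labels = []
        for conn in (6, 26):
            grid, _, _ = _classified_grid(traj)
            cs.label_components(grid, conn)
            flat = grid.voxel_index_of(np.array([[5.0, 5.0, 5.0]]))[0]
            pocket_labels.append(int(grid.labels.ravel()[flat]))
        assert pocket_labels[0] == pocket_labels[1] > 0


class TestDetectCavity:
    def test_pocket_volume_equals_oracle_flood_fill(self, box_pocket):
        traj, _ = box_pocket
        grid, _, coords = _classified_grid(traj)
        cs.label_components(grid)
        site = cs.ActiveSiteSpec(TRIAD).atom_indices(traj)
        cav = cs.detect_cavity(grid, coords, site, seed_distance=8.0)
        oracle = bfs_components(grid.state == STATE_FREE, 26)
        # the pocket is the oracle component containing the box center
        flat = grid.voxel_index_of(np.array([[5.0, 5.0, 5.0]]))[0]
        want = np.flatnonzero(oracle.ravel() == oracle.ravel()[flat])
        assert np.array_equal(cav.cavity_voxels, want)
        assert cav.volume == pytest.approx(len(want) * 0.5**3)

    def test_no_free_voxels_near_site_gives_zero(self, box_pocket):
        traj, _ = box_pocket
        grid, _, coords = _classified_grid(traj)
        cs.label_components(grid)
        site = cs.ActiveSiteSpec(TRIAD).atom_indices(traj)
        cav = cs.detect_cavity(grid, coords, site, seed_distance=0.1)
        assert cav.volume == 0.0 and cav.n_components_in_seed_zone == 0

    def test_gate_closed_splits_seed_zone(self, gated_shells):
        _, _, closed_traj, _ = gated_shells
        series = run_cavity(closed_traj)
        cav, _ = series.records[0]
        assert cav.n_components_in_seed_zone == 2
        assert len(cav.component_volumes) == 2

    def test_monotonicity_atom_inside_cavity_never_grows_it(self, box_pocket):
        traj, _ = box_pocket
        base = run_cavity(traj).records[0][0].volume
        blocked = cs.Trajectory(
            atoms=traj.atoms
            + [
                cs.Atom(
                    serial=traj.n_atoms, name="C", element="C", residue_name="WAL",
                    residue_id=1, chain="A", mass=12.011, vdw_radius=1.7, role="protein",
                )
            ],
            frames=[cs.Frame(np.vstack([traj.coordinates(0), [[5.0, 5.0, 5.0]]]))],
        )
        assert run_cavity(blocked).records[0][0].volume < base

    def test_scale_invariance_volume_times_eight(self, box_pocket):
        traj, _ = box_pocket
        prot = cs.select(traj, role="protein")
        site = cs.ActiveSiteSpec(TRIAD).atom_indices(traj)

        def volume(coords, radii, spacing, padding, seed_d):
            grid = cs.build_grid(coords, prot, spacing=spacing, padding=padding)
            cs.classify_voxels(grid, coords, prot, radii, traj.heavy_mask)
            cs.label_components(grid)
            return cs.detect_cavity(grid, coords, site, seed_distance=seed_d).volume

        v1 = volume(traj.coordinates(0), traj.radii, 0.5, 3.0, 8.0)
        v2 = volume(2 * traj.coordinates(0), 2 * traj.radii, 1.0, 6.0, 16.0)
        assert v2 == pytest.approx(8 * v1)


class TestOccupancy:
    def test_planted_atoms_recovered_exactly(self):
        shell, _ = cs.make_shell(cs.ShellSpec())
        crowd = cs.place_solvent(
            shell, cs.SolventSpec(n_molecules=5, heavy_atoms_per_molecule=1, seed=2)
        )
        sol = cs.select(crowd, role="solvent", heavy=True)
        cav, occ = run_cavity(crowd, solvent_idx=sol).records[0]
        assert occ.heavy_atoms_in_cavity == 5
        assert occ.density == pytest.approx(5 / (cav.volume * 1e-3))

    def test_no_solvent_zero_density(self, box_pocket):
        traj, _ = box_pocket
        _, occ = run_cavity(traj).records[0]
        assert occ.heavy_atoms_in_cavity == 0 and occ.density == 0.0

    def test_density_invariant_under_spacing(self):
        shell, _ = cs.make_shell(cs.ShellSpec())
        crowd = cs.place_solvent(
            shell, cs.SolventSpec(n_molecules=8, heavy_atoms_per_molecule=1, seed=5)
        )
        sol = cs.select(crowd, role="solvent", heavy=True)
        d = []
        for spacing in (0.5, 0.25):
            _, occ = run_cavity(crowd, spacing=spacing, solvent_idx=sol).records[0]
            d.append(occ.density)
        # counts identical; densities differ only through volume convergence
        assert abs(d[0] - d[1]) / d[1] < 0.2


class TestTimeseries:
    def test_static_frames_zero_sd(self, box_pocket):
        traj, _ = box_pocket
        static = cs.jitter(traj, sigma=0.0, n_frames=3, seed=0)
        series = run_cavity(static)
        vols = [c.volume for c, _ in series.records]
        assert len(set(vols)) == 1
        assert series.summary()["sd_volume_A3"] == 0.0

    def test_jittered_volumes_stay_near_frame_zero(self, box_pocket):
        traj, _ = box_pocket
        moving = cs.jitter(traj, sigma=0.1, n_frames=4, seed=11)
        series = run_cavity(moving)
        vols = np.array([c.volume for c, _ in series.records])
        assert np.all(np.abs(vols - vols[0]) <= 0.10 * vols[0])

    def test_gated_trajectory_alternating_components(self, gated_shells):
        open_traj, _, closed_traj, _ = gated_shells
        two = cs.make_two_state(open_traj, closed_traj, "ABAB")
        series = run_cavity(two)
        assert [c.n_components_in_seed_zone for c, _ in series.records] == [1, 2, 1, 2]


class TestConvergence:
    def test_volume_converges_to_ground_truth(self, box_pocket):
        traj, gt = box_pocket
        errors = []
        for spacing in (1.0, 0.5, 0.25):
            vol = run_cavity(traj, spacing=spacing).records[0][0].volume
            errors.append(abs(vol - gt.free_volume_A3) / gt.free_volume_A3)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] <= 0.05
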