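"""Rg, hydrogen bonds, pair distances, RMSD and clustering vs closed forms
and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cavistat as cs
from cavistat.descriptors import pairwise_rmsd_matrix

from oracles import daura_reference, quaternion_rmsd


def _traj_from_frames(frames, elements=None, names=None, resids=None):
    n = len(frames[0])
    elements = elements or ["C"] * n
    names = names or elements
    resids = resids or [1] * n
    atoms = [
        cs.Atom(serial=i, name=names[i], element=elements[i], residue_name="UNK",
                residue_id=resids[i], chain="A", mass=12.011, vdw_radius=1.7,
                role="protein")
        for i in range(n)
    ]
    return cs.Trajectory(
        atoms=atoms, frames=[cs.Frame(np.asarray(f, float), time_index=k)
                             for k, f in enumerate(frames)]
    )


class TestRadiusOfGyration:
    def test_two_unit_masses_two_angstrom_apart(self):
        coords = np.array([[0, 0, 0], [2, 0, 0]], float)
        rg = cs.radius_of_gyration(coords, [0, 1], mass_weighted=False)
        assert rg == pytest.approx(1.0, abs=1e-12)

    def test_square_corners(self):
        coords = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        rg = cs.radius_of_gyration(coords, range(4), mass_weighted=False)
        assert rg == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_single_atom_zero(self):
        assert cs.radius_of_gyration(np.zeros((1, 3)), [0], mass_weighted=False) == 0.0

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            cs.radius_of_gyration(np.zeros((3, 3)), [], mass_weighted=False)

    def test_mass_weighting_pulls_towards_heavy_atom(self):
        coords = np.array([[0, 0, 0], [2, 0, 0]], float)
        rg = cs.radius_of_gyration(coords, [0, 1], masses=np.array([15.999, 1.008]))
        # com sits near the heavy atom, weighted spread < unweighted 1.0
        assert 0 < rg < 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3))
        masses = rng.uniform(1, 16, size=12)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = pts @ q.T + rng.normal(size=3)
        a = cs.radius_of_gyration(pts, range(12), masses)
        b = cs.radius_of_gyration(moved, range(12), masses)
        assert a == pytest.approx(b, abs=1e-9)


class TestHBonds:
    def _oho(self, d_ha, angle_deg):
        """Donor O, its H, acceptor O with a chosen H···A distance/angle."""
        h = np.array([1.0, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)  # D-H···A angle
        acc = h + d_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
        frames = [np.array([[0.0, 0, 0], h, acc])]
        return _traj_from_frames(frames, elements=["O", "H", "O"],
                                 names=["OG", "HG", "OD1"], resids=[1, 1, 2])

    def test_collinear_bond_detected(self):
        traj = self._oho(2.0, 180.0)
        bonds = cs.detect_hbonds(traj, 0, donors=[0], acceptors=[2])
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_atom, b.hydrogen_atom, b.acceptor_atom) == (0, 1, 2)
        assert b.distance_HA == pytest.approx(2.0)
        assert b.angle_DHA == pytest.approx(180.0)

    def test_long_distance_rejected(self):
        assert cs.detect_hbonds(self._oho(3.0, 180.0), 0, [0], [2]) == []

    def test_bent_geometry_rejected(self):
        assert cs.detect_hbonds(self._oho(2.0, 90.0), 0, [0], [2]) == []

    def test_donor_without_hydrogen_warns_and_skips(self):
        frames = [np.array([[0.0, 0, 0], [2.5, 0, 0]])]
        traj = _traj_from_frames(frames, elements=["O", "O"], resids=[1, 2])
        with pytest.warns(UserWarning, match="no resolvable hydrogen"):
            assert cs.detect_hbonds(traj, 0, [0], [1]) == []

    def test_input_order_invariance(self):
        traj = self._oho(2.0, 170.0)
        a = cs.detect_hbonds(traj, 0, [0], [2])
        b = cs.detect_hbonds(traj, 0, [0], [2, 0])
        assert [(x.donor_atom, x.acceptor_atom) for x in a] == [
            (x.donor_atom, x.acceptor_atom) for x in b
        ]

    def test_count_timeseries_tracks_broken_bond(self):
        good = self._oho(2.0, 180.0)
        broken = self._oho(3.5, 180.0)
        traj = cs.make_two_state(good, broken, "AAB")
        counts = cs.hbond_count_timeseries(traj, [0], [2])
        assert counts.tolist() == [1, 1, 0]
        assert cs.hbond_occupancy(traj, 0, 2) == pytest.approx(2 / 3)


class TestTriadDistances:
    def test_constructed_pair_distance(self):
        frames = [np.array([[0.0, 0, 0], [2.8, 0, 0]])]
        traj = _traj_from_frames(frames, elements=["O", "N"], names=["OG", "NE2"],
                                 resids=[105, 224])
        df = cs.triad_distances(traj, [((105, "OG"), (224, "NE2"))])
        assert df["105:OG-224:NE2"].iloc[0] == pytest.approx(2.8)

    def test_pulled_apart_series_is_arithmetic(self):
        frames = [np.array([[0.0, 0, 0], [2.0 + k, 0, 0]]) for k in range(4)]
        traj = _traj_from_frames(frames, elements=["O", "N"], names=["OG", "NE2"],
                                 resids=[105, 224])
        df = cs.triad_distances(traj, [((105, "OG"), (224, "NE2"))])
        np.testing.assert_allclose(df["105:OG-224:NE2"], [2, 3, 4, 5])

    def test_missing_atom_named_in_error(self):
        traj = _traj_from_frames([np.zeros((2, 3))], resids=[105, 224])
        with pytest.raises(ValueError, match="NE2"):
            cs.triad_distances(traj, [((105, "C"), (224, "NE2"))])


class TestSuperposeRmsd:
    def test_identical_frames_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        r, rot, trans = cs.superpose_rmsd(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_rotation_removed(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        r, _, _ = cs.superpose_rmsd(pts, pts @ rot90.T + [1, 2, 3])
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        b = a.copy()
        b[0] += [1.0, 0, 0]
        r, _, _ = cs.superpose_rmsd(a, b)
        assert r == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.5, size=(6, 3))
        rab, _, _ = cs.superpose_rmsd(a, b)
        rba, _, _ = cs.superpose_rmsd(b, a)
        assert rab == pytest.approx(rba, abs=1e-9)
        assert rab == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            cs.superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_no_reflection(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored configuration
        _, rot, _ = cs.superpose_rmsd(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestClustering:
    def test_identical_frames_one_cluster(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        traj = _traj_from_frames([pts] * 3)
        res = cs.cluster_conformations(traj, np.arange(5), cutoff=0.5)
        assert res.n_clusters == 1
        assert res.medoids == [0]
        assert res.sizes == [3]

    def test_two_far_states_two_clusters(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 3))
        b = a + np.array([10.0, 0, 0]) * np.array([[1], [-1], [1], [-1], [1]])
        traj = _traj_from_frames([a, a, b, b])
        res = cs.cluster_conformations(traj, np.arange(5), cutoff=1.0)
        assert res.n_clusters == 2
        assert res.assignments.tolist() == [0, 0, 1, 1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_matches_naive_reference_on_small_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        centers = [rng.normal(size=(6, 3)), rng.normal(size=(6, 3)) + 5]
        frames = [centers[k % 2] + rng.normal(scale=0.05, size=(6, 3)) for k in range(9)]
        traj = _traj_from_frames(frames)
        cutoff = 1.0
        res = cs.cluster_conformations(traj, np.arange(6), cutoff)
        mat = pairwise_rmsd_matrix(traj, np.arange(6))
        medoids, clusters = daura_reference(mat, cutoff)
        assert sorted(res.medoids) == sorted(medoids)
        got = {tuple(np.flatnonzero(res.assignments == c)) for c in range(res.n_clusters)}
        want = {tuple(m) for m in clusters}
        assert got == want

    def test_sizes_sum_to_frame_count(self):
        rng = np.random.default_rng(6)
        frames = [rng.normal(size=(5, 3)) for _ in range(7)]
        traj = _traj_from_frames(frames)
        res = cs.cluster_conformations(traj, np.arange(5), cutoff=0.8)
        assert sum(res.sizes) == 7
        assert sorted(res.sizes, reverse=True) == res.sizes
        for cid, m in enumerate(res.medoids):
            assert res.assignments[m] == cid
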