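import numpy as np
import pytest

from fenmor.core import Atom, Selection, Structure, Trajectory
from fenmor.geometry import (chi2, com_track, delta_z, dihedral, min_distance,
                             place_dihedral, superpose_rmsd, vertical_angle)

from conftest import random_rigid


def point_structure(points, names=None, elements=None, resids=None):
    n = len(points)
    names = names or [f"C{i}" for i in range(n)]
    elements = elements or ["C"] * n
    resids = resids or [1] * n
    atoms = [Atom(names[i], elements[i], resids[i], "XXX", "A", np.asarray(points[i], float))
             for i in range(n)]
    return Structure(atoms)


def one_frame_traj(st):
    return Trajectory(st, [st.coords])


def sel(*idx):
    return Selection(tuple(idx))


class TestMinDistance:
    def test_three_four_five(self):
        st = point_structure([(0, 0, 0), (3, 4, 0)])
        assert min_distance(one_frame_traj(st), sel(0), sel(1))[0] == pytest.approx(5.0)

    def test_min_of_pairs(self):
        st = point_structure([(0, 0, 0), (10, 0, 0), (2, 0, 0)])
        assert min_distance(one_frame_traj(st), sel(0), sel(1, 2))[0] == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(-5, 5, (10, 3))
        st = point_structure(pts)
        a, b = sel(0, 1, 2, 3, 4), sel(5, 6, 7, 8, 9)
        got = min_distance(one_frame_traj(st), a, b)[0]
        brute = min(np.linalg.norm(pts[i] - pts[j])
                    for i in a.atom_indices for j in b.atom_indices)
        assert got == pytest.approx(brute, abs=1e-12)

    def test_empty_selection_named(self):
        st = point_structure([(0, 0, 0)])
        with pytest.raises(ValueError, match="selection B"):
            min_distance(one_frame_traj(st), sel(0), Selection((), label="B"))


class TestDeltaZ:
    def test_hand_com_arithmetic(self):
        # equal-mass receptor pseudo-atoms at z=0 and z=10, ligand at z=9
        st = point_structure([(0, 0, 0), (0, 0, 10), (5, 5, 9)])
        dz = delta_z(one_frame_traj(st), sel(2), sel(0, 1), excluded_resids=())
        assert dz[0] == pytest.approx(4.0)

    def test_translation_invariance(self):
        st = point_structure([(0, 0, 0), (0, 0, 10), (5, 5, 9)])
        moved = st.with_coords(st.coords + np.array([7.0, -2.0, 13.0]))
        a = delta_z(one_frame_traj(st), sel(2), sel(0, 1), excluded_resids=())
        b = delta_z(one_frame_traj(moved), sel(2), sel(0, 1), excluded_resids=())
        assert a[0] == pytest.approx(b[0])

    def test_zero_when_coms_level(self):
        st = point_structure([(0, 0, 4), (0, 0, 6), (9, 9, 5)])
        dz = delta_z(one_frame_traj(st), sel(2), sel(0, 1), excluded_resids=())
        assert dz[0] == pytest.approx(0.0, abs=1e-12)

    def test_exclusions_removing_everything_raise(self):
        st = point_structure([(0, 0, 0), (0, 0, 10), (5, 5, 9)], resids=[60, 60, 900])
        with pytest.raises(ValueError, match="every receptor atom"):
            delta_z(one_frame_traj(st), sel(2), sel(0, 1), excluded_resids=((52, 65),))

    def test_terminal_residues_excluded(self, small_traj):
        traj, _, toy = small_traj
        lig, rec = toy.ligand_selection(), toy.receptor_selection()
        with_excl = delta_z(traj, lig, rec)
        without = delta_z(traj, lig, rec, excluded_resids=())
        # the terminal tails sit at extreme z, so including them shifts dZ
        assert abs(with_excl.mean() - without.mean()) > 0.3


class TestVerticalAngle:
    @pytest.mark.parametrize("direction,expect", [
        ((0, 0, 1), 0.0), ((1, 0, 0), 90.0),
        ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), 45.0),
    ])
    def test_rod_angles(self, direction, expect):
        d = np.asarray(direction)
        pts = [k * d for k in range(5)] + [k * d + (0.01, 0, 0) for k in range(5)]
        st = point_structure(pts)
        with np.errstate(all="ignore"):
            ang = vertical_angle(one_frame_traj(st), sel(*range(10)))[0]
        assert ang == pytest.approx(expect, abs=0.5)

    def test_collinear_warns(self):
        pts = [(0, 0, k) for k in range(4)]
        st = point_structure(pts)
        with pytest.warns(UserWarning, match="collinear"):
            ang = vertical_angle(one_frame_traj(st), sel(0, 1, 2, 3))[0]
        assert ang == pytest.approx(0.0, abs=1e-6)


class TestDihedralChi2:
    def test_cis_is_zero(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([1.0, 1, 0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tor", [90.0, -90.0, 120.0, 179.5, -135.0])
    def test_place_then_measure(self, tor):
        p0, p1, p2 = np.zeros(3), np.array([1.5, 0, 0]), np.array([2.0, 1.4, 0.2])
        p3 = place_dihedral(p0, p1, p2, 1.4, 112.0, tor)
        assert dihedral(p0, p1, p2, p3) == pytest.approx(tor, abs=1e-9)

    def test_matches_biopython_oracle(self, rng):
        from Bio.PDB.vectors import Vector, calc_dihedral
        for _ in range(20):
            p = rng.uniform(-3, 3, (4, 3))
            ref = np.degrees(calc_dihedral(*(Vector(*x) for x in p)))
            assert dihedral(*p) == pytest.approx(ref, abs=1e-9)

    def test_chi2_of_constructed_trp(self, toy):
        assert chi2(toy.structure, 293) == pytest.approx(120.0, abs=1e-6)

    def test_mirror_negates_chi2(self, toy):
        mirrored = toy.structure.with_coords(toy.structure.coords * np.array([1, 1, -1]))
        assert chi2(mirrored, 293) == pytest.approx(-chi2(toy.structure, 293), abs=1e-9)

    def test_missing_atom_named(self):
        st = Structure([Atom(n, "C", 293, "TRP", "A", p) for n, p in
                        [("CA", np.zeros(3)), ("CB", np.ones(3)), ("CG", np.array([2., 2, 2]))]])
        with pytest.raises(KeyError, match="CD1"):
            chi2(st, 293)


class TestSuperposeRmsd:
    def test_identity(self, rng):
        pts = rng.uniform(-5, 5, (8, 3))
        tr, rmsd = superpose_rmsd(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_pure_rotation_recovered(self, rng):
        pts = rng.uniform(-5, 5, (8, 3))
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        tr, rmsd = superpose_rmsd(pts @ rot.T, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_svd_superimposer_oracle(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer as SVD
        mob, ref = rng.uniform(-5, 5, (10, 3)), rng.uniform(-5, 5, (10, 3))
        sup = SVD()
        sup.set(ref, mob)
        sup.run()
        _, got = superpose_rmsd(mob, ref)
        assert got == pytest.approx(float(sup.get_rms()), abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        mob, ref = rng.uniform(-5, 5, (10, 3)), rng.uniform(-5, 5, (10, 3))
        _, ab = superpose_rmsd(mob, ref)
        _, ba = superpose_rmsd(ref, mob)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_too_few_fit_atoms(self):
        with pytest.raises(ValueError, match="3 fit atoms"):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestComTrack:
    def test_stride_counting(self):
        st = point_structure([(0, 0, 0), (1, 0, 0)])
        traj = Trajectory(st, [st.coords + k for k in range(100)], frame_interval=1.0)
        df = com_track(traj, [sel(0)], sel(0, 1), stride_ns=10.0)
        assert len(df) == 10

    def test_single_atom_track_is_relative_coordinate(self):
        st = point_structure([(0, 0, 0), (4, 0, 0)], elements=["C", "C"])
        traj = Trajectory(st, [st.coords])
        df = com_track(traj, [sel(1)], sel(1), stride_ns=1.0)
        assert np.allclose(df[["x", "y", "z"]].to_numpy(), 0.0)

    def test_bad_stride_suggests_nearest(self):
        st = point_structure([(0, 0, 0)])
        traj = Trajectory(st, [st.coords] * 4, frame_interval=1.0)
        with pytest.raises(ValueError, match="nearest valid stride"):
            com_track(traj, [sel(0)], sel(0), stride_ns=2.5)


class TestRigidMotionInvariance:
    """All metrics invariant under translation; distances/RMSD under any
    rotation; dZ and vertical angle under rotation about z."""

    def test_distance_and_rmsd_under_general_rigid_motion(self, small_traj, rng):
        traj, _, toy = small_traj
        rot, trans = random_rigid(rng)
        short = Trajectory(traj.topology, traj.frames[:20])
        moved = Trajectory(traj.topology, short.frames @ rot.T + trans)
        amine, od = toy.amine_selection(), toy.carboxylate_selection()
        assert np.allclose(min_distance(short, amine, od),
                           min_distance(moved, amine, od), atol=1e-9)
        lig = toy.ligand_selection()
        for f in (3, 17):
            _, a = superpose_rmsd(short.frames[f], short.frames[0], fit_selection=lig)
            _, b = superpose_rmsd(moved.frames[f], moved.frames[0], fit_selection=lig)
            assert a == pytest.approx(b, abs=1e-9)

    def test_dz_and_angle_under_z_rotation(self, small_traj, rng):
        traj, _, toy = small_traj
        th = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        trans = rng.uniform(-10, 10, 3)
        short = Trajectory(traj.topology, traj.frames[:20])
        moved = Trajectory(traj.topology, short.frames @ rot.T + trans)
        lig, rec = toy.ligand_selection(), toy.receptor_selection()
        assert np.allclose(delta_z(short, lig, rec), delta_z(moved, lig, rec), atol=1e-9)
        assert np.allclose(vertical_angle(short, lig), vertical_angle(moved, lig),
                           atol=1e-6)
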