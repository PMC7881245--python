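import numpy as np
import pytest

from fenmor.core import Atom, Structure, Trajectory
from fenmor.pocket import (BONDI_VDW_RADII, InclusionBox, align_to_reference,
                           pocket_volume, volume_trajectory)

BOX = InclusionBox(center=(0.0, 0.0, 8.0), sides=(12.0, 12.0, 15.0))


def atom(name, el, resid, xyz, resname="ALA"):
    return Atom(name, el, resid, resname, "A", np.asarray(xyz, float))


def far_structure():
    """Protein far outside the box: volume should be the full box."""
    return Structure([atom("CA", "C", 1, (100, 100, 100))])


class TestPocketVolume:
    def test_empty_box_full_volume(self):
        res = pocket_volume(far_structure(), BOX, spacing=1.0)
        assert res.volume == pytest.approx(12 * 12 * 15)
        assert res.n_points_total == 2160

    def test_occluding_slab_zero(self):
        atoms = [atom(f"C{i}_{j}_{k}", "C", 1, (i - 6, j - 6, 2 * k))
                 for i in range(13) for j in range(13) for k in range(9)]
        st = Structure(atoms)
        res = pocket_volume(st, BOX, spacing=1.0)
        assert res.volume == 0.0

    def test_single_atom_sphere_vs_analytic(self):
        big = InclusionBox(center=(0, 0, 0), sides=(10.0, 10.0, 10.0))
        st = Structure([atom("S", "S", 1, (0.0, 0.0, 0.0))])  # r = 1.8
        r = BONDI_VDW_RADII["S"]
        res = pocket_volume(st, big, spacing=0.25)
        excluded = big.sides[0] ** 3 - res.volume
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        assert excluded == pytest.approx(analytic, rel=0.05)

    def test_probe_radius_inflates_exclusion(self):
        big = InclusionBox(center=(0, 0, 0), sides=(10.0, 10.0, 10.0))
        st = Structure([atom("C1", "C", 1, (0.0, 0.0, 0.0))])
        v0 = pocket_volume(st, big, spacing=0.5).volume
        v1 = pocket_volume(st, big, spacing=0.5, probe_radius=1.4).volume
        assert v1 < v0

    def test_strip_removes_ligand(self):
        st = Structure([atom("C1", "C", 900, (0, 0, 8), resname="LIG")])
        kept = pocket_volume(st, BOX, spacing=1.0)
        stripped = pocket_volume(st, BOX, spacing=1.0, strip_resnames=["LIG"])
        assert stripped.volume == pytest.approx(12 * 12 * 15)
        assert kept.volume < stripped.volume

    def test_hydrogens_ignored(self):
        st = Structure([atom("H1", "H", 1, (0, 0, 8))])
        assert pocket_volume(st, BOX).volume == pytest.approx(12 * 12 * 15)

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            pocket_volume(far_structure(), BOX, spacing=0.0)
        with pytest.raises(ValueError):
            pocket_volume(far_structure(), BOX, spacing=13.0)

    def test_monotone_in_atoms_added(self, rng):
        pts = rng.uniform(-5, 5, (12, 3)) + np.array([0, 0, 8.0])
        vols = []
        for n in (3, 6, 12):
            st = Structure([atom(f"C{i}", "C", 1, pts[i]) for i in range(n)])
            vols.append(pocket_volume(st, BOX).volume)
        assert vols[0] >= vols[1] >= vols[2]

    def test_monotone_in_box_size(self):
        st = Structure([atom("C1", "C", 1, (0, 0, 8))])
        small = InclusionBox((0, 0, 8), (6, 6, 6))
        big = InclusionBox((0, 0, 8), (14, 14, 14))
        assert (pocket_volume(st, small).volume <= pocket_volume(st, big).volume)

    def test_grid_convergence_under_refinement(self, rng):
        pts = rng.uniform(-4, 4, (8, 3)) + np.array([0, 0, 8.0])
        st = Structure([atom(f"C{i}", "C", 1, pts[i]) for i in range(8)])
        v1 = pocket_volume(st, BOX, spacing=1.0).volume
        v05 = pocket_volume(st, BOX, spacing=0.5).volume
        assert abs(v1 - v05) / v05 < 0.05


def site_structure(rot=None, shift=(0, 0, 0)):
    """Three binding-site residues with CA plus one bulky sidechain atom."""
    ca = np.array([[0.0, 0, 8], [4, 0, 6], [0, 4, 6]])
    extra = np.array([[1.0, 1, 7]])
    coords = np.vstack([ca, extra])
    if rot is not None:
        coords = coords @ rot.T
    coords = coords + np.asarray(shift)
    atoms = [atom("CA", "C", 147, coords[0]), atom("CA", "C", 297, coords[1]),
             atom("CA", "C", 293, coords[2]), atom("CB", "C", 147, coords[3])]
    return Structure(atoms)


class TestAlignment:
    SITE = (147, 293, 297)

    def test_self_alignment_identity(self):
        st = site_structure()
        out = align_to_reference(st, st, self.SITE)
        assert np.allclose(out.coords, st.coords, atol=1e-9)

    def test_rotation_recovered(self, rng):
        from conftest import random_rigid
        rot, trans = random_rigid(rng)
        ref = site_structure()
        moved = site_structure(rot=rot, shift=trans)
        back = align_to_reference(moved, ref, self.SITE)
        assert np.allclose(back.coords, ref.coords, atol=1e-9)

    def test_matches_kabsch_oracle(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer
        rot, trans = random_rigid_pair = __import__("conftest").random_rigid(rng)
        ref = site_structure()
        moved = site_structure(rot=rot, shift=trans)
        sup = SVDSuperimposer()
        sup.set(ref.coords[:3], moved.coords[:3])
        sup.run()
        r, t = sup.get_rotran()
        oracle = moved.coords @ r + t
        got = align_to_reference(moved, ref, self.SITE).coords
        assert np.allclose(got, oracle, atol=1e-9)

    def test_missing_ca_listed(self):
        st = site_structure()
        with pytest.raises(KeyError, match="999"):
            align_to_reference(st, st, (147, 999))

    def test_volume_invariant_under_rigid_motion_with_alignment(self, rng):
        from conftest import random_rigid
        ref = site_structure()
        v_ref = pocket_volume(ref, BOX).volume
        rot, trans = random_rigid(rng)
        moved = site_structure(rot=rot, shift=trans)
        v_moved = pocket_volume(align_to_reference(moved, ref, self.SITE), BOX).volume
        assert v_moved == pytest.approx(v_ref)


class TestVolumeTrajectory:
    def test_static_trajectory_sd_zero(self):
        st = site_structure()
        traj = Trajectory(st, [st.coords] * 12, frame_interval=5.0)
        results, mean, sd = volume_trajectory(traj, st, BOX, every_ns=5,
                                              window_ns=50, site_residues=(147, 293, 297))
        assert sd == 0.0

    def test_snapshot_counting(self):
        st = site_structure()
        traj = Trajectory(st, [st.coords] * 60, frame_interval=1.0)
        results, _, _ = volume_trajectory(traj, st, BOX, every_ns=5, window_ns=50,
                                          site_residues=(147, 293, 297))
        assert len(results) == 10

    def test_breathing_pocket_two_point_average(self):
        open_st = site_structure()
        closed = open_st.with_coords(
            np.vstack([open_st.coords[:3], [[0.0, 0.0, 8.0]]]))
        frames = [open_st.coords, closed.coords] * 5
        traj = Trajectory(open_st, frames, frame_interval=1.0)
        results, mean, _ = volume_trajectory(traj, open_st, BOX, every_ns=1,
                                             window_ns=10, site_residues=(147, 293, 297))
        v_open = pocket_volume(open_st, BOX).volume
        v_closed = pocket_volume(closed, BOX).volume
        assert mean == pytest.approx((v_open + v_closed) / 2.0)

    def test_window_longer_than_trajectory(self):
        st = site_structure()
        traj = Trajectory(st, [st.coords] * 4, frame_interval=1.0)
        with pytest.raises(ValueError, match="window"):
            volume_trajectory(traj, st, BOX, every_ns=1, window_ns=50,
                              site_residues=(147, 293, 297))
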