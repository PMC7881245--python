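import numpy as np
import pytest

from fenmor.contacts import (BinaryProfile, ContactProfile, ResidueId,
                             contact_profile, crystal_contact_profile,
                             filter_profile, fingerprint_matrix, frame_contact,
                             tanimoto, tanimoto_matrix)
from fenmor.core import Atom, LigandGroupMap, Selection, Structure, Trajectory


def rid(resid, resname="XXX", chain="A"):
    return ResidueId(chain, resid, resname)


def two_residue_system(residue_offset=3.0):
    """An Asp-like sidechain near the ligand plus a far Leu-like one."""
    atoms = [
        Atom("CB", "C", 10, "ASP", "A", np.array([residue_offset, 0.0, 0.0])),
        Atom("OD1", "O", 10, "ASP", "A", np.array([residue_offset, 0.5, 0.0])),
        Atom("CB", "C", 20, "LEU", "A", np.array([50.0, 0.0, 0.0])),
        Atom("N1", "N", 900, "FEN", "L", np.zeros(3)),
        Atom("C2", "C", 900, "FEN", "L", np.array([0.0, 1.2, 0.0])),
    ]
    st = Structure(atoms)
    lig = Selection((3, 4), label="ligand")
    return st, lig


class TestFrameContact:
    @pytest.mark.parametrize("d,expect", [(4.4, True), (4.5, True), (4.6, False)])
    def test_cutoff_boundary(self, d, expect):
        st, lig = two_residue_system(residue_offset=d)
        traj = Trajectory(st, [st.coords])
        res = Selection((0, 1))
        # nearest pair is (CB at [d,0,0], N1 at origin) = d exactly
        assert frame_contact(traj.frames[0], Selection((0,)), Selection((3,))) is (d <= 4.5)

    def test_empty_selection_raises(self):
        st, lig = two_residue_system()
        with pytest.raises(ValueError, match="empty"):
            frame_contact(st.coords, Selection(()), lig)


class TestContactProfile:
    def test_known_pattern_mean(self):
        st, lig = two_residue_system()
        near = st.coords.copy()
        far = st.coords.copy()
        far[0:2, 0] += 20.0  # push the Asp sidechain out of range
        traj = Trajectory(st, [near] * 5 + [far] * 5)
        prof = contact_profile(traj, None, lig)
        assert prof.fractions[rid(10, "ASP")] == pytest.approx(0.5)
        assert prof.fractions[rid(20, "LEU")] == 0.0

    def test_zero_fraction_residue_listed(self):
        st, lig = two_residue_system()
        prof = contact_profile(Trajectory(st, [st.coords]), None, lig)
        assert rid(20, "LEU") in prof.fractions

    def test_window_validation(self):
        st, lig = two_residue_system()
        traj = Trajectory(st, [st.coords] * 4)
        with pytest.raises(ValueError, match="window"):
            contact_profile(traj, None, lig, window=(3, 3))

    def test_monotone_in_cutoff(self, small_traj):
        traj, _, toy = small_traj
        sub = Trajectory(traj.topology, traj.frames[:50])
        lig = toy.ligand_selection()
        prev = None
        for cutoff in (3.0, 4.5, 6.0, 8.0):
            prof = contact_profile(sub, None, lig, cutoff=cutoff)
            if prev is not None:
                for r, f in prof.fractions.items():
                    assert f >= prev.fractions[r] - 1e-12
            prev = prof

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ContactProfile({rid(1): 1.2})


class TestFilterProfile:
    def test_basic_threshold(self):
        p = ContactProfile({rid(1, "A"): 0.3, rid(2, "B"): 0.2})
        assert filter_profile([p]) == [rid(1, "A")]

    def test_at_least_one_rule(self):
        p1 = ContactProfile({rid(1, "A"): 0.3, rid(2, "B"): 0.2})
        p2 = ContactProfile({rid(1, "A"): 0.0, rid(2, "B"): 0.26})
        assert filter_profile([p1, p2]) == [rid(1, "A"), rid(2, "B")]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            filter_profile([])


class TestFingerprint:
    def test_single_frame_toy(self):
        st, lig = two_residue_system()
        traj = Trajectory(st, [st.coords])
        groups = LigandGroupMap({"piperidine": ["N1"], "phenethyl": ["C2"]},
                                amine_atom="N1")
        fp = fingerprint_matrix(traj, groups, None, lig, occupancy_threshold=0.5)
        assert fp.loc["piperidine", "ASP10"] == 1
        assert fp.loc["piperidine", "LEU20"] == 0

    def test_threshold_one_requires_every_frame(self):
        st, lig = two_residue_system()
        near, far = st.coords.copy(), st.coords.copy()
        far[0:2, 0] += 20.0
        traj = Trajectory(st, [near] * 9 + [far])
        groups = LigandGroupMap({"piperidine": ["N1", "C2"]}, amine_atom="N1")
        fp = fingerprint_matrix(traj, groups, None, lig, occupancy_threshold=1.0)
        assert fp.loc["piperidine", "ASP10"] == 0

    def test_unknown_group_atoms_listed(self):
        st, lig = two_residue_system()
        traj = Trajectory(st, [st.coords])
        groups = LigandGroupMap({"piperidine": ["N1", "C99"]}, amine_atom="N1")
        with pytest.raises(KeyError, match="C99"):
            fingerprint_matrix(traj, groups, None, lig)

    def test_compositional_oracle_on_toy_trajectory(self, small_traj):
        """Matrix entries equal an independent per-frame brute-force count."""
        from scipy.spatial.distance import cdist
        traj, _, toy = small_traj
        sub = Trajectory(traj.topology, traj.frames[:40])
        lig = toy.ligand_selection()
        fp = fingerprint_matrix(sub, toy.groups, None, lig, occupancy_threshold=0.25)
        topo = sub.topology
        lig_set = set(int(i) for i in lig.indices)
        for gname, names in toy.groups.groups.items():
            gidx = [i for i in lig.indices if topo.atoms[i].name in names]
            for rlabel in fp.columns:
                ridx = [i for i, a in enumerate(topo.atoms)
                        if f"{a.residue_name}{a.residue_seq}" == rlabel
                        and i not in lig_set and a.is_heavy
                        and a.name not in ("N", "CA", "C", "O", "OXT")]
                if not ridx:
                    continue
                hits = sum(cdist(sub.frames[f][ridx], sub.frames[f][gidx]).min() <= 4.5
                           for f in range(sub.n_frames))
                expect = int(hits / sub.n_frames >= 0.25)
                assert fp.loc[gname, rlabel] == expect, (gname, rlabel)


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        a = BinaryProfile({rid(1): 1, rid(2): 0, rid(3): 1})
        assert tanimoto(a, a) == 1.0

    def test_disjoint_supports_zero(self):
        a = BinaryProfile({rid(1): 1, rid(2): 0})
        b = BinaryProfile({rid(1): 0, rid(2): 1})
        assert tanimoto(a, b) == 0.0

    def test_worked_example(self):
        a = BinaryProfile({rid(i): v for i, v in enumerate((1, 1, 0, 1))})
        b = BinaryProfile({rid(i): v for i, v in enumerate((1, 0, 1, 1))})
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_union_alignment_absent_residue_is_zero(self):
        a = BinaryProfile({rid(1): 1})
        b = BinaryProfile({rid(1): 1, rid(2): 1})
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_both_all_zero_raises(self):
        a = BinaryProfile({rid(1): 0})
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto(a, a)

    def test_matrix_symmetric_unit_diagonal(self):
        a = BinaryProfile({rid(1): 1, rid(2): 0})
        b = BinaryProfile({rid(1): 1, rid(2): 1})
        m = tanimoto_matrix({"a": a, "b": b})
        assert m.loc["a", "b"] == m.loc["b", "a"]
        assert m.loc["a", "a"] == 1.0


class TestCrystalProfile:
    def test_equals_one_frame_contact_profile(self, toy):
        prof = crystal_contact_profile(toy.structure, "FEN")
        traj = Trajectory(toy.structure, [toy.structure.coords])
        ref = contact_profile(traj, None, toy.ligand_selection())
        assert prof.support() == {r for r, f in ref.fractions.items() if f > 0}

    def test_tiny_cutoff_gives_empty_profile(self, toy):
        prof = crystal_contact_profile(toy.structure, "FEN", cutoff=0.1)
        assert prof.support() == set()

    def test_missing_ligand_raises(self, toy):
        with pytest.raises(ValueError, match="not found"):
            crystal_contact_profile(toy.structure, "XYZ")
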