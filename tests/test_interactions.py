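"""Geometric contact detection against hand geometry and a brute-force oracle."""
import numpy as np
import pytest

import oracle
from conftest import make_topology
from yap8dna.errors import ConfigurationError
from yap8dna.interactions import (DetectionCriteria, detect_all, detect_hbonds,
                                  detect_hydrophobic, detect_saltbridges)
from yap8dna.structures_io import Trajectory


def _pair_top(p_atoms, d_atoms, p_res=("ASN", 20), d_res=("DT", 7)):
    atoms = [(n, e, p_res[1], p_res[0], "A", "monomer1") for n, e in p_atoms]
    atoms += [(n, e, d_res[1], d_res[0], "W", "strandW") for n, e in d_atoms]
    return make_topology(atoms, regions=None)


class TestHbondGeometry:
    def test_collinear_donor_h_acceptor(self):
        top = _pair_top([("ND2", "N"), ("HD21", "H")], [("O4", "O")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]], float)
        events = detect_hbonds(coords, top)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.9)
        assert events[0].angle == pytest.approx(180.0)

    def test_perpendicular_hydrogen_fails_angle(self):
        top = _pair_top([("ND2", "N"), ("HD21", "H")], [("O4", "O")])
        coords = np.array([[0, 0, 0], [0, 1.0, 0], [2.9, 0, 0]], float)
        assert detect_hbonds(coords, top) == []

    def test_boundary_distance_inclusive(self):
        top = _pair_top([("ND2", "N"), ("HD21", "H")], [("O4", "O")])
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]], float)
        assert len(detect_hbonds(coords, top)) == 1

    def test_hydrogen_free_distance_mode(self):
        top = _pair_top([("NZ", "N")], [("OP1", "O")], p_res=("LYS", 8))
        coords = np.array([[0, 0, 0], [3.4, 0, 0]], float)
        assert len(detect_hbonds(coords, top)) == 1
        with pytest.raises(ConfigurationError, match="hbond_dist_only"):
            detect_hbonds(coords, top, DetectionCriteria(hbond_dist_only=None))

    def test_dna_can_donate(self):
        # thymine N3-H3 donating to a glutamine side-chain oxygen
        top = _pair_top([("OE1", "O")], [("N3", "N"), ("H3", "H")],
                        p_res=("GLN", 30))
        coords = np.array([[2.8, 0, 0], [0, 0, 0], [1.0, 0, 0]], float)
        events = detect_hbonds(coords, top)
        assert len(events) == 1
        assert events[0].protein == ("monomer1", 30, "GLN")


class TestSaltBridge:
    def _arg_phos(self, dist):
        top = _pair_top([("NH1", "N")], [("OP1", "O")], p_res=("ARG", 11))
        coords = np.array([[0, 0, 0], [dist, 0, 0]], float)
        return detect_saltbridges(coords, top)

    def test_below_cutoff(self):
        assert len(self._arg_phos(3.8)) == 1

    def test_above_cutoff(self):
        assert self._arg_phos(4.2) == []

    def test_boundary_inclusive(self):
        assert len(self._arg_phos(4.0)) == 1

    def test_group_level_single_event(self):
        # both phosphate oxygens within range -> still one residue-pair event
        top = _pair_top([("NZ", "N")], [("OP1", "O"), ("OP2", "O")],
                        p_res=("LYS", 8))
        coords = np.array([[0, 0, 0], [3.5, 0, 0], [3.9, 0, 0]], float)
        events = detect_saltbridges(coords, top)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(3.5)


class TestHydrophobic:
    def test_single_atom_pseudo_residues(self):
        top = _pair_top([("CD1", "C")], [("C7", "C")], p_res=("LEU", 26))
        near = np.array([[0, 0, 0], [5.9, 0, 0]], float)
        far = np.array([[0, 0, 0], [6.1, 0, 0]], float)
        assert len(detect_hydrophobic(near, top)) == 1
        assert detect_hydrophobic(far, top) == []

    def test_multiatom_com_distance(self):
        # Leu side chain CG/CD1/CD2 (equal masses) vs thymine C7:
        # COM of the three carbons is their centroid
        top = _pair_top([("CG", "C"), ("CD1", "C"), ("CD2", "C")],
                        [("C7", "C")], p_res=("LEU", 26))
        tri = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]], float)
        centroid = tri.mean(axis=0)
        target = centroid + np.array([5.5, 0, 0])
        events = detect_hydrophobic(np.vstack([tri, target]), top)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(5.5, abs=1e-12)

    def test_undefined_residue_skipped(self):
        top = _pair_top([("CB", "C")], [("C7", "C")], p_res=("GLY", 10))
        coords = np.array([[0, 0, 0], [1.0, 0, 0]], float)
        assert detect_hydrophobic(coords, top) == []


def _random_interface_topology():
    """Mixed-chemistry residues for oracle comparison (~90 atoms)."""
    protein = [
        ("ARG", 7, [("N", "N"), ("H", "H"), ("O", "O"), ("NE", "N"), ("HE", "H"),
                    ("NH1", "N"), ("HH11", "H"), ("NH2", "N"), ("HH21", "H")]),
        ("LYS", 8, [("N", "N"), ("O", "O"), ("NZ", "N")]),
        ("ASN", 20, [("N", "N"), ("H", "H"), ("O", "O"), ("ND2", "N"),
                     ("HD21", "H"), ("OD1", "O")]),
        ("GLN", 25, [("NE2", "N"), ("HE21", "H"), ("OE1", "O")]),
        ("LEU", 26, [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")]),
        ("SER", 29, [("OG", "O"), ("HG", "H"), ("O", "O")]),
    ]
    dna = [
        ("DT", 7, [("OP1", "O"), ("OP2", "O"), ("O4'", "O"), ("N3", "N"),
                   ("H3", "H"), ("O2", "O"), ("O4", "O"), ("C7", "C"),
                   ("C5", "C"), ("C6", "C"), ("C2", "C"), ("C4", "C"), ("N1", "N")]),
        ("DA", 9, [("OP1", "O"), ("N1", "N"), ("N3", "N"), ("N7", "N"),
                   ("N6", "N"), ("H61", "H"), ("C2", "C"), ("C8", "C"),
                   ("N9", "N"), ("C4", "C"), ("C5", "C"), ("C6", "C")]),
        ("DG", 8, [("OP1", "O"), ("OP2", "O"), ("N1", "N"), ("H1", "H"),
                   ("N2", "N"), ("H21", "H"), ("O6", "O"), ("N3", "N"),
                   ("N7", "N"), ("C8", "C"), ("N9", "N"), ("C2", "C"),
                   ("C4", "C"), ("C5", "C"), ("C6", "C")]),
        ("DC", 11, [("OP1", "O"), ("O2", "O"), ("N3", "N"), ("N4", "N"),
                    ("H41", "H"), ("C2", "C"), ("C4", "C"), ("C5", "C"),
                    ("C6", "C"), ("N1", "N")]),
    ]
    atoms = []
    for rname, ridx, alist in protein:
        atoms += [(n, e, ridx, rname, "A", "monomer1") for n, e in alist]
    for rname, ridx, alist in dna:
        atoms += [(n, e, ridx, rname, "W", "strandW") for n, e in alist]
    return make_topology(atoms, regions=None)


class TestBruteForceOracle:
    """Spatially random frames: the detectors must agree event-for-event
    with an independent plain-loop all-pairs scan."""

    def test_fifty_random_frames(self):
        top = _random_interface_topology()
        rng = np.random.default_rng(42)
        for _ in range(50):
            coords = rng.uniform(0, 11.0, size=(top.n_atoms, 3))
            got_hb = detect_hbonds(coords, top)
            exp_hb = oracle.hbond_events(top, coords)
            per_pair = {}
            for ev in got_hb:
                per_pair[(ev.protein, ev.dna)] = per_pair.get((ev.protein, ev.dna), 0) + 1
            exp_per_pair = {}
            for p, d, *_ in exp_hb:
                exp_per_pair[(p, d)] = exp_per_pair.get((p, d), 0) + 1
            assert per_pair == exp_per_pair

            got_sb = {(ev.protein, ev.dna) for ev in detect_saltbridges(coords, top)}
            assert got_sb == oracle.saltbridge_events(top, coords)

            got_hp = {(ev.protein, ev.dna) for ev in detect_hydrophobic(coords, top)}
            assert got_hp == oracle.hydrophobic_events(top, coords)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        top = _random_interface_topology()
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 11.0, size=(top.n_atoms, 3))
        rot = Rotation.random(rng=rng)
        moved = rot.apply(coords) + np.array([13.0, -7.0, 4.0])

        def signature(c):
            evs = (detect_hbonds(c, top) + detect_saltbridges(c, top)
                   + detect_hydrophobic(c, top))
            return sorted((e.protein, e.dna, e.itype, round(e.distance, 6))
                          for e in evs)

        assert signature(coords) == signature(moved)

    def test_cutoff_monotonicity(self):
        top = _random_interface_topology()
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 11.0, size=(top.n_atoms, 3))
        base = DetectionCriteria()
        wide = DetectionCriteria(hbond_heavy_dist=3.6, hbond_dist_only=4.2,
                                 salt_dist=5.0, hydrophobic_com_dist=7.5)

        def keys(crit):
            evs = (detect_hbonds(coords, top, crit)
                   + detect_saltbridges(coords, top, crit)
                   + detect_hydrophobic(coords, top, crit))
            return {(e.protein, e.dna, e.itype) for e in evs}

        assert keys(base) <= keys(wide)


class TestDetectAll:
    def test_two_simultaneous_hbonds_count_two(self):
        # two donor branches of one arginine on two thymine acceptors
        top = _pair_top([("NH1", "N"), ("HH11", "H"), ("NH2", "N"), ("HH21", "H")],
                        [("O2", "O"), ("O4", "O")], p_res=("ARG", 22))
        coords = np.array([[0, 0, 0], [1, 0, 0],       # NH1, HH11
                           [0, 8, 0], [1, 8, 0],       # NH2, HH21
                           [2.9, 0, 0], [2.9, 8, 0]],  # O2, O4
                          float)[None]
        # keep the arginine out of salt-bridge range of nothing: no phosphate
        traj = Trajectory(top, coords)
        series = detect_all(traj)
        key = (("monomer1", 22, "ARG"), ("strandW", 7, "DT"), "hbond")
        assert set(series) == {key}
        assert series[key].counts.tolist() == [2]

    def test_dna_only_topology_yields_nothing(self):
        top = make_topology([("OP1", "O", 1, "DT", "W", "strandW")], regions=None)
        traj = Trajectory(top, np.zeros((2, 1, 3)))
        assert detect_all(traj) == {}
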