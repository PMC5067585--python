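import numpy as np
import pytest

from ifaceprof.interactions import (
    DegenerateGeometryError,
    NoSideChainError,
    Thresholds,
    detect_aromatic,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
    hbond_geometry,
    sidechain_com,
)
from ifaceprof.structure_io import DEFAULT_MASSES

from conftest import make_bare_residue_frame, make_frame, random_frame
from oracles import (
    oracle_aromatic,
    oracle_hbond_geometry,
    oracle_hbonds,
    oracle_hydrophobic,
    oracle_salt_bridges,
    oracle_sidechain_com,
)


class TestHbondGeometry:
    def test_collinear(self):
        d, a = hbond_geometry((0, 0, 0), (0.1, 0, 0), (0.3, 0, 0))
        assert d == pytest.approx(0.3)
        assert a == pytest.approx(0.0)

    def test_right_angle(self):
        d, a = hbond_geometry((0, 0, 0), (0.1, 0, 0), (0, 0.3, 0))
        assert d == pytest.approx(0.3)
        assert a == pytest.approx(90.0)

    def test_coincident_donor_hydrogen_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            hbond_geometry((0, 0, 0), (0, 0, 0), (0.3, 0, 0))

    def test_against_trigonometric_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            d, h, a = rng.normal(size=(3, 3))
            if np.linalg.norm(h - d) < 1e-6 or np.linalg.norm(a - d) < 1e-6:
                continue
            got = hbond_geometry(d, h, a)
            want = oracle_hbond_geometry(d, h, a)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)


class TestDetectHbonds:
    def test_single_collinear_donor_acceptor(self, table):
        # Ser OG-HG collinear with a partner backbone O at 0.30 nm.
        frame = make_bare_residue_frame(
            [("SER", "A", 1, [("CB", "C", (-0.15, 0, 0)), ("OG", "O", (0, 0, 0)),
                              ("HG", "H", (0.096, 0, 0))]),
             ("ALA", "A", 2, [("O", "O", (0.30, 0, 0))])]
        )
        events = detect_hbonds(frame, table)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "hbond"
        assert ev.distance == pytest.approx(0.30)
        assert ev.angle == pytest.approx(0.0, abs=1e-9)

    def test_threshold_is_strict(self, table):
        frame = make_bare_residue_frame(
            [("SER", "A", 1, [("OG", "O", (0, 0, 0)), ("HG", "H", (0.096, 0, 0))]),
             ("ALA", "A", 2, [("O", "O", (0.36, 0, 0))])]
        )
        assert detect_hbonds(frame, table) == []
        boundary = make_bare_residue_frame(
            [("SER", "A", 1, [("OG", "O", (0, 0, 0)), ("HG", "H", (0.096, 0, 0))]),
             ("ALA", "A", 2, [("O", "O", (0.35, 0, 0))])]
        )
        assert detect_hbonds(boundary, table) == []

    def test_angle_criterion_excludes_bent_geometry(self, table):
        frame = make_bare_residue_frame(
            [("SER", "A", 1, [("OG", "O", (0, 0, 0)), ("HG", "H", (0, 0.096, 0))]),
             ("ALA", "A", 2, [("O", "O", (0.30, 0, 0))])]
        )
        assert detect_hbonds(frame, table) == []  # 90 degrees at the donor

    def test_donor_without_hydrogen_skipped_or_strict(self, table):
        frame = make_bare_residue_frame(
            [("SER", "A", 1, [("OG", "O", (0, 0, 0))]),
             ("ALA", "A", 2, [("O", "O", (0.30, 0, 0))])]
        )
        assert detect_hbonds(frame, table) == []
        with pytest.raises(ValueError, match="no resolvable hydrogen"):
            detect_hbonds(frame, table, strict=True)


class TestSidechainCom:
    def test_single_atom_side_chain(self, table):
        frame = make_bare_residue_frame(
            [("ALA", "A", 1, [("CB", "C", (1.0, 1.0, 1.0))])]
        )
        com = sidechain_com(frame.residues()[0], frame, table)
        np.testing.assert_allclose(com, [1.0, 1.0, 1.0])

    def test_equal_mass_atoms_average(self, table):
        frame = make_bare_residue_frame(
            [("LEU", "A", 1, [("CD1", "C", (0, 0, 0)), ("CD2", "C", (0, 0, 2.0))])]
        )
        com = sidechain_com(frame.residues()[0], frame, table)
        np.testing.assert_allclose(com, [0, 0, 1.0])

    def test_leucine_mass_weighted_mean_by_hand(self, table):
        atoms = [("CB", "C", (0.0, 0.0, 0.0)), ("CG", "C", (0.15, 0.0, 0.0)),
                 ("CD1", "C", (0.25, 0.1, 0.0)), ("CD2", "C", (0.25, -0.1, 0.0)),
                 ("HB2", "H", (-0.05, 0.09, 0.0))]
        frame = make_bare_residue_frame([("LEU", "A", 1, atoms)])
        m = {"C": DEFAULT_MASSES["C"], "H": DEFAULT_MASSES["H"]}
        num = sum(np.array(x) * m[el] for _, el, x in atoms)
        den = sum(m[el] for _, el, _ in atoms)
        com = sidechain_com(frame.residues()[0], frame, table)
        np.testing.assert_allclose(com, num / den, atol=1e-9)

    def test_glycine_has_no_side_chain(self, table):
        frame = make_frame([("GLY", "A", 1, (0, 0, 0))])
        with pytest.raises(NoSideChainError):
            sidechain_com(frame.residues()[0], frame, table)


class TestDetectHydrophobic:
    def test_distance_bands(self, table):
        near = make_bare_residue_frame(
            [("ALA", "A", 1, [("CB", "C", (0, 0, 0))]),
             ("ALA", "A", 2, [("CB", "C", (0.45, 0, 0))])]
        )
        assert len(detect_hydrophobic(near, table)) == 1
        far = make_bare_residue_frame(
            [("ALA", "A", 1, [("CB", "C", (0, 0, 0))]),
             ("ALA", "A", 2, [("CB", "C", (0.55, 0, 0))])]
        )
        assert detect_hydrophobic(far, table) == []

    def test_five_residues_on_a_line(self, table):
        # 0.3 nm spacing: 4 adjacent pairs qualify, next-nearest at 0.6 nm do not.
        frame = make_bare_residue_frame(
            [("ALA", "A", i + 1, [("CB", "C", (0.3 * i, 0, 0))]) for i in range(5)]
        )
        events = detect_hydrophobic(frame, table)
        assert len(events) == 4
        assert all(
            abs(e.residue_a[1] - e.residue_b[1]) == 1 for e in events
        )

    def test_glycine_never_participates(self, table):
        frame = make_frame(
            [("GLY", "A", 1, (0, 0, 0)), ("ALA", "A", 2, (0.2, 0, 0)),
             ("ALA", "A", 3, (0.5, 0, 0))]
        )
        events = detect_hydrophobic(frame, table)
        assert all("GLY" not in (e.res_name_a, e.res_name_b) for e in events)


class TestDetectSaltBridges:
    def test_distance_bands(self, table):
        near = make_bare_residue_frame(
            [("ARG", "A", 1, [("NH1", "N", (0, 0, 0))]),
             ("PTR", "B", 2, [("O1P", "O", (0.35, 0, 0))])]
        )
        events = detect_salt_bridges(near, table)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(0.35)
        far = make_bare_residue_frame(
            [("ARG", "A", 1, [("NH1", "N", (0, 0, 0))]),
             ("PTR", "B", 2, [("O1P", "O", (0.45, 0, 0))])]
        )
        assert detect_salt_bridges(far, table) == []

    def test_grid_matches_exhaustive_oracle(self, table, thresholds):
        rng = np.random.default_rng(3)
        residues = []
        n = 1
        for i in range(3):
            residues.append(("ARG", "A", n, tuple(rng.uniform(0, 0.8, 3))))
            n += 1
        for i in range(3):
            residues.append(("GLU", "B", n, tuple(rng.uniform(0, 0.8, 3))))
            n += 1
        frame = make_frame(residues)
        got = {("salt_bridge", e.residue_a, e.residue_b)
               for e in detect_salt_bridges(frame, table, thresholds)}
        assert got == oracle_salt_bridges(frame, table, thresholds)

    def test_histidine_only_charged_when_flagged(self, table):
        frame = make_bare_residue_frame(
            [("HIS", "A", 1, [("ND1", "N", (0, 0, 0)), ("NE2", "N", (0.1, 0, 0))]),
             ("GLU", "B", 2, [("OE1", "O", (0.3, 0, 0))])]
        )
        assert detect_salt_bridges(frame, table) == []
        th = Thresholds(his_protonated=True)
        assert len(detect_salt_bridges(frame, table, th)) == 1


class TestDetectAromatic:
    def test_phe_pair_is_aromatic(self, table):
        frame = make_frame(
            [("PHE", "A", 1, (0, 0, 0)), ("PHE", "B", 2, (0.45, 0, 0))]
        )
        hydro = detect_hydrophobic(frame, table)
        arom = detect_aromatic(frame, table)
        assert len(arom) >= 1
        assert {(e.residue_a, e.residue_b) for e in arom} <= {
            (e.residue_a, e.residue_b) for e in hydro
        }
        assert all(e.atoms_a == "RING" for e in arom)

    def test_phe_leu_is_hydrophobic_only(self, table):
        frame = make_frame(
            [("PHE", "A", 1, (0, 0, 0)), ("LEU", "B", 2, (0.25, 0, 0))]
        )
        assert len(detect_hydrophobic(frame, table)) >= 1
        assert detect_aromatic(frame, table) == []

    def test_aromatic_subset_property_random_frames(self, table, thresholds):
        rng = np.random.default_rng(11)
        for _ in range(10):
            frame = random_frame(rng, 10)
            arom = {(e.residue_a, e.residue_b) for e in detect_aromatic(frame, table, thresholds)}
            hydro = {(e.residue_a, e.residue_b) for e in detect_hydrophobic(frame, table, thresholds)}
            assert arom <= hydro


class TestDetectorProperties:
    def test_atom_order_invariance(self, table, thresholds):
        rng = np.random.default_rng(5)
        frame = random_frame(rng, 12)
        perm = rng.permutation(frame.n_atoms)
        from ifaceprof.structure_io import Frame

        shuffled = Frame(
            [frame.topology[i] for i in perm], frame.coords[perm], index=0
        )
        for detector in (detect_hbonds, detect_salt_bridges, detect_hydrophobic, detect_aromatic):
            a = [(e.pair_key, e.atoms_a, e.atoms_b, round(e.distance, 9)) for e in detector(frame, table, thresholds)]
            b = [(e.pair_key, e.atoms_a, e.atoms_b, round(e.distance, 9)) for e in detector(shuffled, table, thresholds)]
            assert sorted(a) == sorted(b)

    def test_threshold_monotonicity(self, table):
        rng = np.random.default_rng(8)
        frame = random_frame(rng, 12)
        small = Thresholds(hbond_dist=0.25, hbond_angle=20, hydrophobic_dist=0.4, saltbridge_dist=0.3)
        base = Thresholds()
        large = Thresholds(hbond_dist=0.45, hbond_angle=45, hydrophobic_dist=0.65, saltbridge_dist=0.5)
        for detector in (detect_hbonds, detect_salt_bridges, detect_hydrophobic):
            sets = [
                {(e.pair_key, e.atoms_a, e.atoms_b) for e in detector(frame, table, th)}
                for th in (small, base, large)
            ]
            assert sets[0] <= sets[1] <= sets[2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_oracle_equivalence(self, table, thresholds, seed):
        rng = np.random.default_rng(seed)
        frame = random_frame(rng, 15)
        got_h = {("hbond", e.residue_a, e.residue_b, e.atoms_a, e.atoms_b)
                 for e in detect_hbonds(frame, table, thresholds)}
        assert got_h == oracle_hbonds(frame, table, thresholds)
        got_p = {("hydrophobic", e.residue_a, e.residue_b)
                 for e in detect_hydrophobic(frame, table, thresholds)}
        assert got_p == oracle_hydrophobic(frame, table, thresholds)
        got_s = {("salt_bridge", e.residue_a, e.residue_b)
                 for e in detect_salt_bridges(frame, table, thresholds)}
        assert got_s == oracle_salt_bridges(frame, table, thresholds)
        got_a = {("aromatic", e.residue_a, e.residue_b)
                 for e in detect_aromatic(frame, table, thresholds)}
        assert got_a == oracle_aromatic(frame, table, thresholds)

    def test_sidechain_com_matches_oracle(self, table):
        rng = np.random.default_rng(9)
        frame = random_frame(rng, 8)
        for res in frame.residues():
            want = oracle_sidechain_com(res, frame, table)
            if want is None:
                continue
            got = sidechain_com(res, frame, table)
            np.testing.assert_allclose(got, want, atol=1e-12)
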