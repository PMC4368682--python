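"""Salt-bridge detection/classification, cross-link scoring, clashes."""

import numpy as np
import pytest

import helixbundle as hb
from helixbundle.errors import ParameterError
from helixbundle.interactions import ACIDIC_ATOMS, BASIC_ATOMS
from helixbundle.structure import AtomRecord, ResidueRecord


def charged_pair(distance, acidic="GLU", basic="LYS"):
    """Minimal two-residue structure: one acidic tip, one basic tip."""
    a_atom = ACIDIC_ATOMS[acidic][0]
    b_atom = BASIC_ATOMS[basic][0]
    residues = [
        ResidueRecord(1, acidic, [
            AtomRecord(1, "CA", "C", [0.0, 0, 0]),
            AtomRecord(2, a_atom, "O", [1.0, 0, 0])]),
        ResidueRecord(5, basic, [
            AtomRecord(3, "CA", "C", [1.0 + distance + 1.0, 0, 0]),
            AtomRecord(4, b_atom, "N", [1.0 + distance, 0, 0])]),
    ]
    return hb.Structure(residues)


def brute_force_bridges(structure, cutoff=4.1):
    """All-pairs O···N scan, the reference for every detection test."""
    found = {}
    for ra in structure.residues:
        names_a = ACIDIC_ATOMS.get(ra.name)
        if not names_a:
            continue
        for rb in structure.residues:
            names_b = BASIC_ATOMS.get(rb.name)
            if not names_b:
                continue
            dmin = min(
                (float(np.linalg.norm(ra.atom(x).coords - rb.atom(y).coords))
                 for x in names_a for y in names_b
                 if ra.atom(x) is not None and rb.atom(y) is not None),
                default=np.inf)
            if dmin <= cutoff:
                found[(ra.index, rb.index)] = dmin
    return found


class TestDetectSaltBridges:
    def test_pair_below_cutoff_detected(self):
        st = charged_pair(3.5)
        bridges = hb.detect_salt_bridges(st)
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.5)

    def test_cutoff_is_exclusive_above(self):
        assert hb.detect_salt_bridges(charged_pair(4.2)) == []
        assert len(hb.detect_salt_bridges(charged_pair(4.1))) == 1

    def test_no_chargeable_residues_is_empty_not_error(self, ideal_helix18):
        st = hb.build_ideal_helix(hb.HelixSpec("g", "GSGSGS"))
        assert hb.detect_salt_bridges(st) == []

    def test_matches_bruteforce_on_fixture(self, planted_fixture):
        st, _ = planted_fixture
        got = {(b.acidic_index, b.basic_index): b.min_distance
               for b in hb.detect_salt_bridges(st)}
        ref = brute_force_bridges(st)
        assert set(got) == set(ref)
        for k in got:
            assert got[k] == pytest.approx(ref[k], abs=1e-9)

    def test_arg_uses_all_guanidinium_nitrogens(self):
        st = charged_pair(3.0, basic="ARG")
        assert len(hb.detect_salt_bridges(st)) == 1


class TestClassifySaltBridges:
    def test_planted_intra_and_inter_counts(self):
        seg = hb.HelixSegmentation([("H1", 1, 10, "helix"), ("H2", 20, 30, "helix")])
        bridges = [
            hb.SaltBridge(2, "GLU", 5, "LYS", 3.0),    # intra H1
            hb.SaltBridge(22, "ASP", 28, "LYS", 3.5),  # intra H2
            hb.SaltBridge(3, "GLU", 25, "ARG", 3.2),   # inter
            hb.SaltBridge(8, "ASP", 21, "LYS", 3.9),   # inter
            hb.SaltBridge(15, "GLU", 27, "LYS", 3.1),  # loop partner -> inter
        ]
        intra, inter, detail = hb.classify_salt_bridges(bridges, seg)
        assert (intra, inter) == (2, 3)
        assert [d.classification for d in detail] == [
            "intra-helix", "intra-helix", "inter-helix", "inter-helix",
            "involves-loop"]
        assert intra + inter == len(bridges)

    def test_empty_list(self):
        seg = hb.HelixSegmentation([("H1", 1, 10, "helix")])
        assert hb.classify_salt_bridges([], seg)[:2] == (0, 0)


class TestWindowedSaltBridges:
    def test_constant_ensemble_equals_single_frame(self):
        st = charged_pair(3.5)
        ens = hb.Ensemble([st, st.copy(), st.copy()])
        single = hb.detect_salt_bridges(st)
        windowed = hb.windowed_salt_bridges(ens, window=3)
        assert [(b.pair, round(b.min_distance, 6)) for b in windowed] == \
               [(b.pair, round(b.min_distance, 6)) for b in single]

    def test_oscillating_pair_mean_four_is_reported(self):
        frames = [charged_pair(3.0), charged_pair(5.0),
                  charged_pair(3.0), charged_pair(5.0)]
        ens = hb.Ensemble(frames)
        got = hb.windowed_salt_bridges(ens, window=4)
        assert len(got) == 1
        assert got[0].min_distance == pytest.approx(4.0)

    def test_window_one_equals_last_frame(self):
        frames = [charged_pair(3.0), charged_pair(6.0)]
        ens = hb.Ensemble(frames)
        assert hb.windowed_salt_bridges(ens, window=1) == []
        frames2 = [charged_pair(6.0), charged_pair(3.0)]
        got = hb.windowed_salt_bridges(hb.Ensemble(frames2), window=1)
        assert len(got) == 1

    def test_matches_per_frame_mean_oracle(self, rng):
        dists = rng.uniform(2.8, 6.0, size=6)
        ens = hb.Ensemble([charged_pair(float(d)) for d in dists])
        got = hb.windowed_salt_bridges(ens, window=6)
        expect = float(np.mean(dists)) <= 4.1
        assert (len(got) == 1) == expect

    def test_bad_window(self):
        ens = hb.Ensemble([charged_pair(3.0)])
        with pytest.raises(ParameterError):
            hb.windowed_salt_bridges(ens, window=0)
        with pytest.raises(ParameterError):
            hb.windowed_salt_bridges(ens, window=2)


class TestCrosslinkConsistency:
    def test_planted_fixture_fully_satisfied(self, planted_fixture):
        st, truth = planted_fixture
        rep = hb.crosslink_consistency(st, truth.planted_crosslinks)
        assert rep.n_satisfied == rep.n_total == len(truth.planted_crosslinks)

    def test_empty_restraints(self, ideal_helix18):
        rep = hb.crosslink_consistency(ideal_helix18, [])
        assert (rep.n_satisfied, rep.n_total) == (0, 0)

    def test_monotone_in_cutoff(self, planted_fixture):
        st, _ = planted_fixture
        pairs = [(2, 53), (9, 75), (16, 31), (2, 75)]
        counts = []
        for cutoff in (5.0, 15.0, 25.0, 60.0):
            restraints = [hb.CrosslinkRestraint.of(a, b, cutoff) for a, b in pairs]
            counts.append(hb.crosslink_consistency(st, restraints).n_satisfied)
        assert counts == sorted(counts)

    def test_ensemble_majority_rule(self, ideal_helix30):
        near = ideal_helix30
        far = ideal_helix30.transform(np.eye(3), np.zeros(3))
        # move residue 30 far away in 2 of 3 frames
        def shifted(d):
            s = ideal_helix30.copy()
            for a in s.residue(30).atoms:
                a.coords = a.coords + np.array([d, 0, 0])
            return s
        r = [hb.CrosslinkRestraint.of(1, 30, 50.0)]
        ens = hb.Ensemble([near, shifted(100.0), shifted(120.0)])
        rep = hb.crosslink_consistency(ens, r)
        assert rep.n_satisfied == 0          # satisfied in only 1/3 frames
        assert rep.series.shape == (1, 3)
        ens2 = hb.Ensemble([near, near.copy(), shifted(100.0)])
        assert hb.crosslink_consistency(ens2, r).n_satisfied == 1

    def test_unresolvable_site_raises(self, ideal_helix18):
        with pytest.raises(hb.errors.SelectionError):
            hb.crosslink_consistency(
                ideal_helix18, [hb.CrosslinkRestraint.of(1, 99)])


class TestClashScore:
    def test_two_close_atoms_in_distant_residues(self):
        st = charged_pair(0.5)  # tips 0.5 Å apart, residues 1 and 5
        assert hb.clash_score(st, threshold=2.4) >= 1

    def test_ideal_helix_clash_free(self, ideal_helix30):
        assert hb.clash_score(ideal_helix30, threshold=2.4) == 0

    def test_monotone_nonincreasing_in_threshold(self, planted_fixture):
        st, _ = planted_fixture
        scores = [hb.clash_score(st, t) for t in (3.5, 3.0, 2.4, 1.5)]
        assert scores == sorted(scores, reverse=True)


class TestRestraintTsv:
    def test_round_trip_with_nt_keyword(self, tmp_path):
        restraints = [hb.CrosslinkRestraint.of("NT", 96),
                      hb.CrosslinkRestraint.of(23, 59, cutoff=15.0)]
        p = tmp_path / "xl.tsv"
        hb.write_restraints_tsv(restraints, p)
        back = hb.read_restraints_tsv(p)
        assert back == restraints
        assert back[0].site_a.atom == "N" and back[0].site_a.index == 1
        assert back[1].cutoff == 15.0
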