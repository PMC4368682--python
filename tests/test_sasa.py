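"""Solvent-accessible surface area and helical-wheel analysis."""

import numpy as np
import pytest

import helixbundle as hb
from helixbundle.errors import InputError, ParameterError, SequenceError
from helixbundle.sasa import KYTE_DOOLITTLE, VDW_RADII, sphere_points
from helixbundle.structure import AtomRecord, ResidueRecord


def atom_structure(coords_elements, name="CA"):
    """Structure with one atom per residue at given (coords, element)."""
    residues = []
    for i, (xyz, el) in enumerate(coords_elements, start=1):
        residues.append(ResidueRecord(i, "GLY", [
            AtomRecord(i, name, el, np.asarray(xyz, float))]))
    return hb.Structure(residues)


def grid_sasa_two_atoms(c1, r1, c2, r2, probe, spacing=0.25):
    """Independent dense-grid oracle: latitude bands of surface points at
    `spacing` Å arc separation on each expanded sphere, excluded by the
    other expanded sphere."""
    total = 0.0
    for (ca, ra, cb, rb) in ((c1, r1 + probe, c2, r2 + probe),
                             (c2, r2 + probe, c1, r1 + probe)):
        area = 0.0
        n_theta = max(int(np.pi * ra / spacing), 4)
        for k in range(n_theta):
            theta = (k + 0.5) * np.pi / n_theta
            ring_r = ra * np.sin(theta)
            circumference = 2.0 * np.pi * ring_r
            n_phi = max(int(circumference / spacing), 4)
            band_area = 2.0 * np.pi * ra ** 2 * (
                np.cos(k * np.pi / n_theta) - np.cos((k + 1) * np.pi / n_theta))
            point_area = band_area / n_phi
            for j in range(n_phi):
                phi = 2.0 * np.pi * (j + 0.5) / n_phi
                p = ca + ra * np.array([np.sin(theta) * np.cos(phi),
                                        np.sin(theta) * np.sin(phi),
                                        np.cos(theta)])
                if np.linalg.norm(p - cb) >= rb:
                    area += point_area
        total += area
    return total


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = atom_structure([((0, 0, 0), "C")])
        # C radius 1.7 + probe 1.4 -> analytic 4*pi*3.1^2
        res = hb.shrake_rupley_sasa(st, probe=1.4, n_points=960)
        analytic = 4.0 * np.pi * 3.1 ** 2
        assert res.total == pytest.approx(analytic, rel=0.02)

    def test_sulfur_sphere_with_larger_radius(self):
        st = atom_structure([((0, 0, 0), "S")], name="SD")
        res = hb.shrake_rupley_sasa(st, probe=1.4, n_points=960)
        analytic = 4.0 * np.pi * (1.8 + 1.4) ** 2
        assert res.total == pytest.approx(analytic, rel=0.02)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell = [(3.0 * p, "C") for p in sphere_points(80)]
        st = atom_structure([((0.0, 0.0, 0.0), "C")] + shell)
        res = hb.shrake_rupley_sasa(st, probe=1.4, n_points=960)
        assert res.per_residue[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("separation", [2.0, 3.4, 5.0])
    def test_two_atom_system_matches_grid_oracle(self, separation):
        c1 = np.zeros(3)
        c2 = np.array([separation, 0.0, 0.0])
        st = atom_structure([(c1, "C"), (c2, "O")])
        res = hb.shrake_rupley_sasa(st, probe=1.4, n_points=960)
        oracle = grid_sasa_two_atoms(c1, VDW_RADII["C"], c2, VDW_RADII["O"], 1.4)
        assert res.total == pytest.approx(oracle, rel=0.03)

    def test_separated_atoms_additive(self):
        st = atom_structure([((0, 0, 0), "C"), ((50, 0, 0), "N"), ((0, 50, 0), "O")])
        res = hb.shrake_rupley_sasa(st, probe=1.4, n_points=960)
        isolated = sum(4.0 * np.pi * (VDW_RADII[e] + 1.4) ** 2
                       for e in ("C", "N", "O"))
        assert res.total == pytest.approx(isolated, rel=0.02)

    def test_adding_an_atom_never_increases_existing_area(self, rng):
        base_atoms = [(rng.normal(scale=3.0, size=3), "C") for _ in range(8)]
        st = atom_structure(base_atoms)
        before = hb.shrake_rupley_sasa(st, n_points=240).per_atom
        st2 = atom_structure(base_atoms + [(np.array([1.0, 0.5, 0.2]), "C")])
        after = hb.shrake_rupley_sasa(st2, n_points=240).per_atom[:8]
        assert np.all(after <= before + 1e-9)

    def test_per_residue_sums_per_atom(self, ideal_helix18):
        res = hb.shrake_rupley_sasa(ideal_helix18, n_points=240)
        assert res.per_residue.sum() == pytest.approx(res.per_atom.sum(), abs=1e-6)

    def test_errors(self):
        st = atom_structure([((0, 0, 0), "H")])
        with pytest.raises(InputError):
            hb.shrake_rupley_sasa(st)


class TestHydrophobicMeanSasa:
    def test_equals_bruteforce_per_residue_loop(self, bundle4_closed):
        got = hb.hydrophobic_mean_sasa(bundle4_closed, n_points=240)
        res = hb.shrake_rupley_sasa(bundle4_closed, n_points=240)
        areas = [a for a, name in zip(res.per_residue, res.residue_names)
                 if name in hb.HYDROPHOBIC_RESIDUES]
        assert got == pytest.approx(float(np.sum(areas)) / len(areas), abs=1e-9)

    def test_buried_and_exposed_mean_arithmetic(self):
        # one LEU enclosed in a shell, one isolated far away
        shell = [(np.array([100, 0, 0]) + 3.0 * p, "C")
                 for p in sphere_points(80)]
        residues = [ResidueRecord(1, "LEU", [AtomRecord(1, "CB", "C", [100.0, 0, 0])]),
                    ResidueRecord(2, "LEU", [AtomRecord(2, "CB", "C", [0.0, 0, 0])])]
        for i, (xyz, el) in enumerate(shell, start=3):
            residues.append(ResidueRecord(i, "GLY", [AtomRecord(i, "C", el, xyz)]))
        st = hb.Structure(residues)
        mean = hb.hydrophobic_mean_sasa(st, n_points=960)
        exposed = 4.0 * np.pi * 3.1 ** 2
        assert mean == pytest.approx(exposed / 2.0, rel=0.03)

    def test_ensemble_averages_frames(self, ideal_helix18):
        single = hb.hydrophobic_mean_sasa(ideal_helix18, n_points=240)
        ens = hb.Ensemble([ideal_helix18, ideal_helix18.copy()])
        assert hb.hydrophobic_mean_sasa(ens, n_points=240) == pytest.approx(single)

    def test_empty_set_rejected(self, ideal_helix18):
        with pytest.raises(ParameterError):
            hb.hydrophobic_mean_sasa(ideal_helix18, hydrophobic_set=set())


class TestHelicalWheel:
    def test_uniform_18_mer_moment_is_zero(self):
        w = hb.helical_wheel("L" * 18)
        assert w.moment_magnitude == pytest.approx(0.0, abs=1e-9)

    def test_single_distinct_residue_sets_direction(self):
        # 17 Ala + 1 Ile at position 8 with a zero-mean scale offset: the
        # moment must point at the Ile angle
        seq = "AAAAAAAIAAAAAAAAAA"
        w = hb.helical_wheel(seq)
        shifted = {k: v - KYTE_DOOLITTLE["A"] for k, v in KYTE_DOOLITTLE.items()}
        w2 = hb.helical_wheel(seq, scale=shifted)
        ile_angle = w.per_residue_angle[seq.index("I")]
        assert w2.moment_angle == pytest.approx(ile_angle, abs=1e-6)

    def test_moment_equals_bruteforce_sum(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(rng.choice(letters, size=25))
        w = hb.helical_wheel(seq)
        mx = sum(KYTE_DOOLITTLE[c] * np.cos(np.radians(100.0 * i))
                 for i, c in enumerate(seq))
        my = sum(KYTE_DOOLITTLE[c] * np.sin(np.radians(100.0 * i))
                 for i, c in enumerate(seq))
        np.testing.assert_allclose(w.moment, [mx, my], atol=1e-9)

    def test_angles_within_wheel(self):
        w = hb.helical_wheel("LKELEDLLKELEDL")
        assert np.all((w.per_residue_angle >= 0) & (w.per_residue_angle < 360))
        assert w.moment_magnitude <= np.abs(w.per_residue_hydrophobicity).sum() + 1e-9

    def test_unknown_letter_rejected(self):
        with pytest.raises(SequenceError):
            hb.helical_wheel("AAZ")


class TestHydrophobicFace:
    def test_face_centres_on_moment_for_amphipathic_segment(self):
        w = hb.helical_wheel(AMPHIPATHIC := "LKELEDLLKELEDLLKEL")
        (lo, hi), _ = hb.hydrophobic_face(w, arc_width=120.0)
        centre = (lo + 60.0) % 360.0
        diff = abs((centre - w.moment_angle + 180.0) % 360.0 - 180.0)
        assert diff <= 20.0

    def test_exhaustive_scan_oracle(self, rng):
        letters = np.array(list("LKEDAVIF"))
        seq = "".join(rng.choice(letters, size=18))
        w = hb.helical_wheel(seq)
        (lo, _hi), _ = hb.hydrophobic_face(w, arc_width=100.0)
        # brute force over integer centres
        best, best_sum = None, -np.inf
        for centre in range(360):
            delta = np.abs((w.per_residue_angle - centre + 180.0) % 360.0 - 180.0)
            s = w.per_residue_hydrophobicity[delta <= 50.0].sum()
            if s > best_sum + 1e-12:
                best, best_sum = centre, s
        assert (lo + 50.0) % 360.0 == pytest.approx(best, abs=1e-6)

    def test_uniform_ties_break_to_zero(self):
        w = hb.helical_wheel("A" * 18)
        (lo, hi), _ = hb.hydrophobic_face(w, arc_width=120.0)
        assert (lo + 60.0) % 360.0 == pytest.approx(0.0)

    def test_bad_arc_width(self):
        w = hb.helical_wheel("A" * 5)
        with pytest.raises(ParameterError):
            hb.hydrophobic_face(w, arc_width=360.0)
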