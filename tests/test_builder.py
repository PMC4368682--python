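"""Ideal-helix construction, topology enumeration, assembly, loop
closure, perturbation and ground-truth fixtures."""

from itertools import permutations

import numpy as np
import pytest

import helixbundle as hb
from helixbundle.builder import (
    LoopSpan,
    _MAX_SPAN_PER_RESIDUE,
    loop_spans,
    spans_from_segmentation,
)
from helixbundle.errors import (
    ClosureError,
    ParameterError,
    SequenceError,
)
from tests.conftest import AMPHIPATHIC_18, four_helix_topology


def dihedral(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, n1 @ n2))


class TestBuildIdealHelix:
    def test_18_residue_default_is_18_over_5(self, ideal_helix18):
        fit = hb.fit_helix_axis(ideal_helix18)
        assert abs(fit.twist_per_residue) == pytest.approx(100.0, abs=1.5)
        assert fit.residues_per_turn == pytest.approx(3.6, abs=0.05)
        assert fit.rise_per_residue == pytest.approx(1.5, abs=0.05)

    def test_single_residue_degenerate(self):
        st = hb.build_ideal_helix(hb.HelixSpec("one", "K"))
        assert len(st) == 1
        names = {a.atom_name for a in st.residues[0].atoms}
        assert {"N", "CA", "C", "O", "CB", "NZ"} <= names

    def test_unknown_letter_rejected(self):
        with pytest.raises(SequenceError):
            hb.HelixSpec("bad", "AXW")

    def test_backbone_dihedrals_and_chirality(self):
        st = hb.build_ideal_helix(hb.HelixSpec("t", "AAAAAA"))
        r = st.residues
        phi = dihedral(r[1].atom("C").coords, r[2].atom("N").coords,
                       r[2].atom("CA").coords, r[2].atom("C").coords)
        psi = dihedral(r[2].atom("N").coords, r[2].atom("CA").coords,
                       r[2].atom("C").coords, r[3].atom("N").coords)
        improper = dihedral(r[2].atom("N").coords, r[2].atom("C").coords,
                            r[2].atom("CA").coords, r[2].atom("CB").coords)
        assert phi == pytest.approx(-63.8, abs=0.1)
        assert psi == pytest.approx(-41.5, abs=0.1)
        # L-amino-acid improper, matching standard residue templates
        assert improper == pytest.approx(120.0, abs=3.0)

    def test_charged_tips_present_at_canonical_distances(self):
        st = hb.build_ideal_helix(hb.HelixSpec("t", "KRDE"))
        expect = {"LYS": ("NZ", 3.9), "ARG": ("NH1", 4.1),
                  "ASP": ("OD1", 2.5), "GLU": ("OE1", 3.1)}
        for res in st.residues:
            name, dist = expect[res.name]
            tip = res.atom(name)
            assert tip is not None
            got = float(np.linalg.norm(tip.coords - res.atom("CB").coords))
            assert got == pytest.approx(dist, abs=1e-6)

    def test_thirty_mer_assigns_helix(self, ideal_helix30):
        assert hb.helix_content(hb.assign_ss(ideal_helix30)) >= 90.0


def brute_force_topology_count(n: int) -> int:
    """Independent oracle: enumerate all assignments of the chain to the
    two-row grid cells, keep nearest-neighbour paths, dedupe reversal."""
    cols = (n + 1) // 2
    cells = [(r, c) for c in range(cols) for r in range(2)][:n]

    def adjacent(a, b):
        return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1

    seen = set()
    for perm in permutations(cells):
        if all(adjacent(perm[i], perm[i + 1]) for i in range(n - 1)):
            seen.add(min(tuple(perm), tuple(reversed(perm))))
    return len(seen)


class TestEnumerateTopologies:
    def test_six_helices_give_eight_configurations(self):
        assert len(hb.enumerate_topologies(6)) == 8

    def test_single_helix_trivial(self):
        tops = hb.enumerate_topologies(1)
        assert len(tops) == 1

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_counts_match_bruteforce_oracle(self, n):
        assert len(hb.enumerate_topologies(n)) == brute_force_topology_count(n)

    def test_deterministic_ids_and_alternating_orientations(self):
        a = hb.enumerate_topologies(4)
        b = hb.enumerate_topologies(4)
        assert [t.pattern_id for t in a] == [t.pattern_id for t in b]
        assert all(t.orientations == [1, -1, 1, -1] for t in a)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            hb.enumerate_topologies(7)
        with pytest.raises(ParameterError):
            hb.enumerate_topologies(0)


class TestAssembleBundle:
    def test_two_helix_packing_distance_read_back(self):
        topo = hb.enumerate_topologies(2)[0].with_helices(
            [hb.HelixSpec("A", AMPHIPATHIC_18), hb.HelixSpec("B", AMPHIPATHIC_18)],
            loops=["GSGS"])
        st = hb.assemble_bundle(topo, packing_distance=10.5)
        fa = hb.fit_helix_axis(st, 1, 18)
        fb = hb.fit_helix_axis(st, 23, 40)
        # antiparallel
        assert fa.direction @ fb.direction < -0.9
        # inter-axis distance = distance between axis origins perpendicular
        # to the (shared) axis direction
        delta = fb.origin - fa.origin
        perp = delta - (delta @ fa.direction) * fa.direction
        assert np.linalg.norm(perp) == pytest.approx(10.5, abs=0.1)

    def test_four_helix_bundle_clash_free(self, bundle4_assembled):
        assert hb.clash_score(bundle4_assembled, threshold=2.4) == 0

    def test_assembly_preserves_helix_internal_geometry(self, bundle4_topology,
                                                        bundle4_assembled):
        ref = hb.build_ideal_helix(bundle4_topology.helices[0])
        placed = [r for r in bundle4_assembled.residues if r.index <= 18]
        ref_d = np.linalg.norm(ref.coords()[:, None] - ref.coords()[None, :], axis=2)
        got = np.array([a.coords for r in placed for a in r.atoms])
        got_d = np.linalg.norm(got[:, None] - got[None, :], axis=2)
        np.testing.assert_allclose(got_d, ref_d, atol=1e-8)

    def test_hydrophobic_faces_buried(self, bundle4_closed):
        """The assembler points each helix's hydrophobic face at the
        bundle core, so hydrophobic residues bury more surface."""
        result = hb.shrake_rupley_sasa(bundle4_closed, n_points=240)
        hydro = {"LEU"}
        polar = {"LYS", "GLU", "ASP"}
        per = dict(zip(result.residue_indices, result.per_residue))
        mean = lambda names: np.mean([
            per[r.index] for r in bundle4_closed.residues if r.name in names])
        assert mean(hydro) < mean(polar)


class TestCloseLoops:
    def test_feasible_loop_closes_tightly(self, bundle4_topology, bundle4_assembled):
        closed = hb.close_loops(bundle4_assembled, loop_spans(bundle4_topology))
        for span in loop_spans(bundle4_topology):
            c = closed.residue(span.end).atom("C").coords
            n = closed.residue(span.end + 1).atom("N").coords
            assert abs(np.linalg.norm(c - n) - 1.329) < 0.3

    def test_backbone_bonds_within_five_percent(self, bundle4_closed):
        standard = {("N", "CA"): 1.458, ("CA", "C"): 1.525}
        for r in bundle4_closed.residues:
            for (a, b), ref in standard.items():
                d = float(np.linalg.norm(r.atom(a).coords - r.atom(b).coords))
                assert abs(d - ref) / ref < 0.05

    def test_one_residue_loop_cannot_span_20_angstroms(self):
        # two anchor residues 20 Å apart joined by a single loop residue
        a = hb.build_ideal_helix(hb.HelixSpec("a", "AAAA"))
        b = a.transform(np.eye(3), np.array([26.0, 0.0, 0.0]))
        residues = [r.copy() for r in a.residues]
        for r in b.residues:
            rc = r.copy()
            rc.index = r.index + 5
            residues.append(rc)
        st = hb.Structure(residues)
        gap = float(np.linalg.norm(st.residue(4).atom("C").coords
                                   - st.residue(6).atom("N").coords))
        assert gap > 2 * _MAX_SPAN_PER_RESIDUE  # arithmetic infeasibility
        with pytest.raises(ClosureError) as err:
            hb.close_loops(st, [LoopSpan(5, 5, "G")])
        assert err.value.min_length is not None and err.value.min_length > 1

    def test_closure_adds_no_clash(self, bundle4_assembled, bundle4_topology):
        closed = hb.close_loops(bundle4_assembled, loop_spans(bundle4_topology))
        assert hb.clash_score(closed) <= hb.clash_score(bundle4_assembled)


class TestPerturb:
    def test_zero_magnitude_is_identity(self, bundle4_closed, bundle4_segmentation):
        out = hb.perturb(bundle4_closed, bundle4_segmentation, 0.0, seed=5)
        np.testing.assert_array_equal(out.coords(), bundle4_closed.coords())

    def test_same_seed_is_bit_identical(self, bundle4_closed, bundle4_segmentation):
        a = hb.perturb(bundle4_closed, bundle4_segmentation, 2.0, seed=11)
        b = hb.perturb(bundle4_closed, bundle4_segmentation, 2.0, seed=11)
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_helix_displacement_bounded_by_transform_composition(
            self, bundle4_closed, bundle4_segmentation):
        mag = 2.0
        out = hb.perturb(bundle4_closed, bundle4_segmentation, mag, seed=7)
        for seg in bundle4_segmentation.helices():
            ref = np.array([a.coords
                            for r in bundle4_closed.residues
                            if seg.start <= r.index <= seg.end
                            for a in r.atoms])
            got = np.array([a.coords for r in out.residues
                            if seg.start <= r.index <= seg.end
                            for a in r.atoms])
            disp = np.linalg.norm(got - ref, axis=1)
            assert disp.max() > 0.0
            # analytic bound: rotation <= mag deg about the centroid plus
            # translation <= mag
            radius = np.linalg.norm(ref - ref.mean(axis=0), axis=1).max()
            bound = mag + 2.0 * radius * np.sin(np.radians(mag) / 2.0)
            assert disp.max() <= bound + 1e-6

    def test_spans_derived_from_segmentation(self, bundle4_closed,
                                             bundle4_segmentation):
        spans = spans_from_segmentation(bundle4_closed, bundle4_segmentation)
        assert [(s.start, s.end) for s in spans] == [(19, 22), (41, 44), (63, 66)]
        assert all(s.kind == "internal" for s in spans)


class TestMakeFixture:
    def test_plants_verified_on_emission(self, planted_fixture):
        st, truth = planted_fixture
        report = hb.crosslink_consistency(st, truth.planted_crosslinks)
        assert report.n_satisfied == report.n_total == 3
        found = {(b.acidic_index, b.basic_index)
                 for b in hb.detect_salt_bridges(st)}
        assert set(map(tuple, truth.planted_salt_bridges)) <= found

    def test_no_plants_gives_plain_bundle(self):
        topo = four_helix_topology()
        st, truth = hb.make_fixture(topo, hb.GroundTruth(), seed=0)
        assert len(st) == 84
        assert truth.planted_crosslinks == [] and truth.planted_salt_bridges == []

    def test_distinct_seeds_distinct_structures(self):
        topo = four_helix_topology()
        truth = hb.GroundTruth(
            planted_crosslinks=[hb.CrosslinkRestraint.of(2, 31)])
        a, _ = hb.make_fixture(topo, truth, seed=1)
        b, _ = hb.make_fixture(topo, truth, seed=2)
        assert not np.allclose(a.coords(), b.coords())
        for st in (a, b):
            rep = hb.crosslink_consistency(st, truth.planted_crosslinks)
            assert rep.n_satisfied == 1
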