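"""Human apolipoprotein A-I reference data and synthetic reconstruction.

Mature human apo A-I is a 243-residue polypeptide whose lipid-free form
is modelled here as a bundled four-helix N-terminal domain (residues
1–192) with a short two-helix C-terminal hairpin (193–243).  This module
carries the sequence, the two published helix segmentations (the
construction ranges and the post-relaxation measurement ranges, which
differ — notably around helix 5), the experimentally named lysine
cross-link pairs and inter-helix salt bridges, and a builder that
reconstructs a full-length model with the package's own pipeline.

The reconstruction is SYNTHETIC: it is built from the sequence and the
segmentation by idealized-helix assembly, rigid-body optimization against
the named interaction plants, and CCD loop closure — it is this package's
stand-in for deposited reference coordinates, not a copy of them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .builder import (
    BundleTopology,
    GroundTruth,
    HelixSpec,
    enumerate_topologies,
    make_fixture,
)
from .errors import GenerationError
from .interactions import CrosslinkRestraint
from .structure import HelixSegmentation, Segment, Structure

__all__ = [
    "APOA1_SEQUENCE",
    "CONSTRUCTION_SEGMENTATION",
    "MEASUREMENT_SEGMENTATION",
    "N_DOMAIN_END",
    "NAMED_CROSSLINKS",
    "NAMED_INTER_BRIDGES",
    "DOMAIN_LINKING_BRIDGES",
    "FRET_DISTANCE_PAIRS",
    "apoa1_topology",
    "build_apoa1_model",
    "truncated",
]

#: Mature human apolipoprotein A-I, 243 residues.
APOA1_SEQUENCE = (
    "DEPPQSPWDRVKDLATVYVDVLKDSGRDYVSQFEGSALGKQLNLKLLDNWDSVTSTFSKL"
    "REQLGPVTQEFWDNLEKETEGLRQEMSKDLEEVKAKVQPYLDDFQKKWQEEMELYRQKVE"
    "PLRAELQEGARQKLHELQEKLSPLGEEMRDRARAHVDALRTHLAPYSDELRQRLAARLEA"
    "LKENGGARLAEYHAKATEHLSTLSEKAKPALEDLRQGLLPVLESFKVSFLSALEEYTKKLNTQ"
)
assert len(APOA1_SEQUENCE) == 243

#: Last residue of the N-terminal helix-bundle domain.
N_DOMAIN_END = 192

#: Helix ranges used to CONSTRUCT the model (six helices, five loops).
CONSTRUCTION_SEGMENTATION = HelixSegmentation([
    Segment("H1", 7, 46), Segment("H2", 48, 82), Segment("H3", 94, 121),
    Segment("H4", 143, 180), Segment("H5", 195, 212), Segment("H6", 220, 240),
])

#: Helix ranges as MEASURED on the relaxed model (the default
#: segmentation for classification); helix 5 in particular differs from
#: the construction range.
MEASUREMENT_SEGMENTATION = HelixSegmentation([
    Segment("H1", 7, 39), Segment("H2", 50, 79), Segment("H3", 98, 123),
    Segment("H4", 140, 186), Segment("H5", 195, 218), Segment("H6", 223, 238),
])

#: The three interpeptide Lys cross-link pairs singled out by the
#: cross-linking/mass-spectrometry comparison (Cβ–Cβ ≤ 20 Å; "NT" is the
#: N-terminal amine of residue 1).
NAMED_CROSSLINKS = [
    CrosslinkRestraint.of("NT", 96),
    CrosslinkRestraint.of(23, 59),
    CrosslinkRestraint.of(96, 226),
]

#: The nine named inter-helix salt bridges (acidic residue, basic residue):
#: a six-bridge N-terminal network plus three bridges linking the C- and
#: N-terminal domains.
NAMED_INTER_BRIDGES = [
    (2, 96), (1, 96), (1, 94), (76, 94), (92, 177), (89, 177),   # N network
    (223, 160), (212, 106), (103, 208),                          # C<->N domain
]

#: The subset of NAMED_INTER_BRIDGES that links the two domains.
DOMAIN_LINKING_BRIDGES = [(223, 160), (212, 106), (103, 208)]

#: FRET-comparison distance pairs (Cα by default), report-only.
FRET_DISTANCE_PAIRS = [(50, 83), (50, 173)]


def _segment_sequences(segmentation: HelixSegmentation
                       ) -> tuple[list[str], list[str], str, str]:
    helices = []
    loops = []
    segs = segmentation.helices()
    n_tail = APOA1_SEQUENCE[: segs[0].start - 1]
    c_tail = APOA1_SEQUENCE[segs[-1].end:]
    for i, s in enumerate(segs):
        helices.append(APOA1_SEQUENCE[s.start - 1: s.end])
        if i + 1 < len(segs):
            loops.append(APOA1_SEQUENCE[s.end: segs[i + 1].start - 1])
    return helices, loops, n_tail, c_tail


def apoa1_topology(pattern_id: str | None = None) -> BundleTopology:
    """A six-helix topology configured with the apo A-I construction
    ranges.  `pattern_id` picks one of the eight enumerated up-down
    arrangements; the default is the arrangement used by the packaged
    reconstruction."""
    topologies = {t.pattern_id: t for t in enumerate_topologies(6)}
    # default: the four N-domain helices form a square bundle with the
    # C-domain hairpin (H5/H6) packed alongside, and every named bridge
    # pair sits on nearest or diagonal positions
    pattern_id = pattern_id or "updown6-2"
    if pattern_id not in topologies:
        raise KeyError(f"unknown pattern {pattern_id!r}; "
                       f"choose from {sorted(topologies)}")
    helices, loops, n_tail, c_tail = _segment_sequences(CONSTRUCTION_SEGMENTATION)
    specs = [HelixSpec(f"H{i + 1}", seq) for i, seq in enumerate(helices)]
    return topologies[pattern_id].with_helices(specs, loops, n_tail, c_tail)


def build_apoa1_model(seed: int = 0, pattern_id: str | None = None,
                      plant_named: bool = True,
                      optimizer_maxiter: int = 25,
                      attempts: int = 3) -> tuple[Structure, GroundTruth]:
    """Reconstruct a full-length lipid-free apo A-I model (synthetic).

    Builds the six construction helices as idealized 18/5 α-helices,
    assembles them on the chosen up-down topology, optimizes the rigid
    placements against the named cross-links and salt bridges
    (`plant_named=True`), and closes the loops.  The placement search is
    stochastic, so up to `attempts` deterministically derived sub-seeds
    are tried; the result is still a pure function of `seed`.  Returns
    the structure and its verified ground truth.
    """
    topo = apoa1_topology(pattern_id)
    truth = GroundTruth(
        planted_crosslinks=list(NAMED_CROSSLINKS) if plant_named else [],
        planted_salt_bridges=list(NAMED_INTER_BRIDGES) if plant_named else [],
    )
    last: Exception | None = None
    for k in range(max(attempts, 1)):
        try:
            return make_fixture(topo, truth, seed=seed + 7919 * k,
                                optimizer_maxiter=optimizer_maxiter)
        except GenerationError as exc:
            last = exc
    raise last


#: Segmentation of the extended-hairpin stand-in (two long arms).
EXTENDED_SEGMENTATION = HelixSegmentation([
    Segment("arm1", 1, 120), Segment("arm2", 124, 243),
])


def build_extended_standin(seed: int = 0) -> Structure:
    """An extended α-helical hairpin over the full sequence (synthetic).

    Two long idealized helical arms (residues 1–120 and 124–243) joined
    by a short turn — a stand-in for the elongated, non-bundled
    conformation seen in the C-terminally truncated crystal form, used
    for ordering comparisons (cross-link violations, hydrophobic
    exposure) against the compact bundle.  Not a model of the crystal
    coordinates.
    """
    topo = enumerate_topologies(2)[0].with_helices(
        [HelixSpec("arm1", APOA1_SEQUENCE[0:120]),
         HelixSpec("arm2", APOA1_SEQUENCE[123:243])],
        loops=[APOA1_SEQUENCE[120:123]])
    st, _ = make_fixture(topo, GroundTruth(), seed=seed)
    st.label = "extended-standin"
    return st


def truncated(structure: Structure, last_residue: int = 184) -> Structure:
    """C-terminally truncated copy (the crystallized construct ends at
    residue 184)."""
    res = [r.copy() for r in structure.residues if r.index <= last_residue]
    return Structure(res, label=f"{structure.label}-trunc{last_residue}")
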