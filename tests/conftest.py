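"""Shared fixtures: small synthetic bundles reused across the suite.

Expensive constructions (the planted four-helix fixture and the
full-length apolipoprotein A-I reconstruction) are session-scoped so the
optimization cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import helixbundle as hb
from helixbundle.builder import loop_spans

AMPHIPATHIC_18 = "LKELEDLLKELEDLLKEL"  # K at 2/9/16, E at 3/5/10/12/17, D at 6/13


def four_helix_topology() -> hb.BundleTopology:
    return hb.enumerate_topologies(4)[0].with_helices(
        [hb.HelixSpec(f"H{i + 1}", AMPHIPATHIC_18) for i in range(4)],
        loops=["GSGS", "GSGS", "GSGS"])


def four_helix_segmentation() -> hb.HelixSegmentation:
    # layout: H1 1-18, loop 19-22, H2 23-40, loop 41-44, H3 45-62,
    # loop 63-66, H4 67-84
    return hb.HelixSegmentation(
        [(f"H{i + 1}", 1 + i * 22, 18 + i * 22, "helix") for i in range(4)])


# plants chosen so partners face each other at matching heights on
# adjacent antiparallel helices
PLANTED_CROSSLINKS = [hb.CrosslinkRestraint.of(2, 31),
                      hb.CrosslinkRestraint.of(9, 53),
                      hb.CrosslinkRestraint.of(16, 75)]
PLANTED_BRIDGES = [(10, 31), (32, 53)]


@pytest.fixture(scope="session")
def bundle4_topology():
    return four_helix_topology()


@pytest.fixture(scope="session")
def bundle4_assembled(bundle4_topology):
    return hb.assemble_bundle(bundle4_topology)


@pytest.fixture(scope="session")
def bundle4_closed(bundle4_topology, bundle4_assembled):
    return hb.close_loops(bundle4_assembled, loop_spans(bundle4_topology))


@pytest.fixture(scope="session")
def bundle4_segmentation():
    return four_helix_segmentation()


@pytest.fixture(scope="session")
def planted_fixture(bundle4_topology):
    truth = hb.GroundTruth(planted_crosslinks=list(PLANTED_CROSSLINKS),
                           planted_salt_bridges=list(PLANTED_BRIDGES))
    return hb.make_fixture(bundle4_topology, truth, seed=1)


@pytest.fixture(scope="session")
def ideal_helix18():
    return hb.build_ideal_helix(hb.HelixSpec("h18", "A" * 18))


@pytest.fixture(scope="session")
def ideal_helix30():
    return hb.build_ideal_helix(hb.HelixSpec("h30", "A" * 30))


@pytest.fixture(scope="session")
def apoa1_reconstruction():
    """Full-length synthetic apo A-I model with the named interactions
    planted (the package's stand-in for deposited reference coordinates).

    If the full nine-bridge plant cannot be realized, a cross-link-only
    reconstruction is returned so the rest of the battery still runs;
    the salt-bridge checks then fail on their own terms.
    """
    from helixbundle import apoa1
    from helixbundle.errors import GenerationError
    try:
        return apoa1.build_apoa1_model(seed=1, attempts=1)
    except GenerationError:
        topo = apoa1.apoa1_topology()
        truth = hb.GroundTruth(planted_crosslinks=list(apoa1.NAMED_CROSSLINKS))
        return hb.make_fixture(topo, truth, seed=1)


@pytest.fixture(scope="session")
def extended_standin():
    """Extended helical-hairpin stand-in (synthetic), the non-bundled
    comparison conformation."""
    from helixbundle import apoa1
    return apoa1.build_extended_standin(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
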