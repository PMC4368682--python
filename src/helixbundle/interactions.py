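"""Salt-bridge detection/classification and cross-link restraint scoring.

Salt bridges: an acidic side-chain carboxylate oxygen (Asp OD1/OD2,
Glu OE1/OE2) within the cutoff (default 4.1 Å) of a basic side-chain
nitrogen (Lys NZ, Arg NE/NH1/NH2); His is excluded.  Each acid–base
residue pair is reported once with its minimum O···N distance.  Works on
full side chains (PDB input) and on the single-tip pseudo-atoms emitted
by the synthetic builder, which reuse the same atom names.

Cross-links: residue-site pairs (Lys → Cβ, the N-terminal amine "NT" →
backbone N of residue 1) with a distance cutoff, default 20 Å.  On
ensembles a restraint counts as satisfied when it holds in at least half
of the frames (majority rule); the per-frame series is always reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError, SegmentationError
from .geometry import Site, pair_distance
from .structure import Ensemble, HelixSegmentation, Structure

__all__ = [
    "SaltBridgeConfig",
    "SaltBridge",
    "CrosslinkRestraint",
    "CrosslinkReport",
    "detect_salt_bridges",
    "classify_salt_bridges",
    "windowed_salt_bridges",
    "crosslink_consistency",
    "clash_score",
    "read_restraints_tsv",
    "write_restraints_tsv",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


@dataclass
class SaltBridgeConfig:
    """Detection parameters: O···N cutoff (Å) and trailing window size."""

    cutoff: float = 4.1
    window_frames: int = 1

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("salt-bridge cutoff must be positive")


@dataclass
class SaltBridge:
    acidic_index: int
    acidic_name: str
    basic_index: int
    basic_name: str
    min_distance: float
    classification: str | None = None  # intra-helix | inter-helix | involves-loop

    @property
    def pair(self) -> tuple[int, int]:
        return (self.acidic_index, self.basic_index)

    def __str__(self) -> str:
        return (f"{self.acidic_name}{self.acidic_index}-"
                f"{self.basic_name}{self.basic_index} ({self.min_distance:.2f} Å)")


def _charged_atom_coords(structure: Structure, table: dict):
    idx, names, coords = [], [], []
    for res in structure.residues:
        atom_names = table.get(res.name)
        if not atom_names:
            continue
        for an in atom_names:
            a = res.atom(an)
            if a is not None:
                idx.append(res.index)
                names.append(res.name)
                coords.append(a.coords)
    return idx, names, np.array(coords) if coords else np.empty((0, 3))


def _pair_min_distances(structure: Structure, reach: float
                        ) -> dict[tuple[int, int], tuple[str, str, float]]:
    """Minimum O···N distance per acidic/basic residue pair within reach."""
    ai, an, ac = _charged_atom_coords(structure, ACIDIC_ATOMS)
    bi, bn, bc = _charged_atom_coords(structure, BASIC_ATOMS)
    out: dict[tuple[int, int], tuple[str, str, float]] = {}
    if len(ac) == 0 or len(bc) == 0:
        return out
    ta, tb = cKDTree(ac), cKDTree(bc)
    for i, js in enumerate(ta.query_ball_tree(tb, reach)):
        for j in js:
            d = float(np.linalg.norm(ac[i] - bc[j]))
            key = (ai[i], bi[j])
            prev = out.get(key)
            if prev is None or d < prev[2]:
                out[key] = (an[i], bn[j], d)
    return out


def detect_salt_bridges(structure: Structure,
                        config: SaltBridgeConfig | None = None) -> list[SaltBridge]:
    """All acid–base pairs with minimum O···N distance ≤ the cutoff.

    Structures without chargeable residues yield an empty list.
    """
    config = config or SaltBridgeConfig()
    pairs = _pair_min_distances(structure, config.cutoff)
    bridges = [SaltBridge(a, an, b, bn, d)
               for (a, b), (an, bn, d) in pairs.items() if d <= config.cutoff]
    bridges.sort(key=lambda s: (s.acidic_index, s.basic_index))
    return bridges


def windowed_salt_bridges(ensemble: Ensemble,
                          config: SaltBridgeConfig | None = None,
                          window: int | None = None) -> list[SaltBridge]:
    """Bridges whose per-frame minimum O···N distance, averaged over the
    trailing `window` frames, is ≤ the cutoff."""
    config = config or SaltBridgeConfig()
    window = window if window is not None else config.window_frames
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > len(ensemble):
        raise ParameterError("window exceeds the frame count")
    frames = ensemble.frames[-window:]
    # pairs must be averaged over every frame of the window, so collect
    # distances with a generous reach and average
    reach = config.cutoff * 3.0
    per_pair: dict[tuple[int, int], list] = {}
    meta: dict[tuple[int, int], tuple[str, str]] = {}
    for f in frames:
        for key, (an, bn, d) in _pair_min_distances(f, reach).items():
            per_pair.setdefault(key, []).append(d)
            meta[key] = (an, bn)
    out = []
    for key, ds in per_pair.items():
        if len(ds) < len(frames):
            # out of reach in some frame: treat the missing frames as the
            # reach bound (a lower bound on the true mean)
            ds = ds + [reach] * (len(frames) - len(ds))
        mean = float(np.mean(ds))
        if mean <= config.cutoff:
            an, bn = meta[key]
            out.append(SaltBridge(key[0], an, key[1], bn, mean))
    out.sort(key=lambda s: (s.acidic_index, s.basic_index))
    return out


def classify_salt_bridges(bridges: list[SaltBridge],
                          segmentation: HelixSegmentation
                          ) -> tuple[int, int, list[SaltBridge]]:
    """Classify bridges against a helix segmentation.

    intra = both partners inside the same helix segment; inter = partners
    in different helices; a partner on a loop counts as inter (loop
    contacts constrain the tertiary arrangement the same way) but is
    tagged "involves-loop" in the detail list.  Returns
    (intra count, inter count, detailed list).
    """
    detail = []
    intra = inter = 0
    for b in bridges:
        ha = segmentation.helix_of(b.acidic_index)
        hb = segmentation.helix_of(b.basic_index)
        out = SaltBridge(**{**b.__dict__})
        if ha is None or hb is None:
            out.classification = "involves-loop"
            inter += 1
        elif ha == hb:
            out.classification = "intra-helix"
            intra += 1
        else:
            out.classification = "inter-helix"
            inter += 1
        detail.append(out)
    return intra, inter, detail


@dataclass(frozen=True)
class CrosslinkRestraint:
    """A cross-linked residue-site pair with a distance cutoff (Å)."""

    site_a: Site
    site_b: Site
    cutoff: float = 20.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("cross-link cutoff must be positive")
        if (self.site_a.index, self.site_a.atom) == (self.site_b.index, self.site_b.atom):
            raise ParameterError("cross-link sites must be distinct")

    @classmethod
    def of(cls, a: str | int, b: str | int, cutoff: float = 20.0
           ) -> "CrosslinkRestraint":
        return cls(Site.parse(a), Site.parse(b), cutoff)

    def label(self) -> str:
        return f"{self.site_a}-{self.site_b}"


@dataclass
class CrosslinkReport:
    restraints: list[CrosslinkRestraint]
    distances: np.ndarray          # representative distance per restraint
    satisfied: np.ndarray          # boolean per restraint
    series: np.ndarray | None = None  # (n_restraints, n_frames) for ensembles

    @property
    def n_satisfied(self) -> int:
        return int(self.satisfied.sum())

    @property
    def n_total(self) -> int:
        return len(self.restraints)

    def to_dict(self) -> dict:
        return {
            "n_satisfied": self.n_satisfied,
            "n_total": self.n_total,
            "restraints": [
                {"pair": r.label(), "cutoff": r.cutoff,
                 "distance": float(d), "satisfied": bool(s)}
                for r, d, s in zip(self.restraints, self.distances, self.satisfied)
            ],
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def crosslink_consistency(target: Structure | Ensemble,
                          restraints: list[CrosslinkRestraint]
                          ) -> CrosslinkReport:
    """Score cross-link restraints against a structure or ensemble.

    Single structure: satisfied ⇔ site distance ≤ cutoff.  Ensemble: the
    per-frame series is computed; satisfied ⇔ the cutoff holds in ≥ 50% of
    frames, and the reported distance is the per-frame minimum.
    """
    if isinstance(target, Structure):
        dists = np.array([pair_distance(target, r.site_a, r.site_b)
                          for r in restraints])
        sat = np.array([d <= r.cutoff for d, r in zip(dists, restraints)],
                       dtype=bool)
        return CrosslinkReport(list(restraints), dists, sat)
    series = np.array([[pair_distance(f, r.site_a, r.site_b) for f in target]
                       for r in restraints]).reshape(len(restraints), len(target))
    sat = np.array([(row <= r.cutoff).mean() >= 0.5
                    for row, r in zip(series, restraints)], dtype=bool)
    dists = series.min(axis=1) if len(restraints) else np.empty(0)
    return CrosslinkReport(list(restraints), dists, sat, series=series)


def clash_score(structure: Structure, threshold: float = 2.4) -> int:
    """Number of non-bonded heavy-atom pairs closer than `threshold` Å.

    Pairs within the same residue or in sequence-adjacent residues
    (separation < 2) are ignored; a clash-free structure scores 0.
    """
    if threshold <= 0:
        raise ParameterError("clash threshold must be positive")
    atoms = []
    owner = []
    for res in structure.residues:
        for a in res.heavy_atoms():
            atoms.append(a.coords)
            owner.append(res.index)
    coords = np.array(atoms)
    owner = np.array(owner)
    tree = cKDTree(coords)
    count = 0
    for i, j in tree.query_pairs(threshold):
        if abs(int(owner[i]) - int(owner[j])) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Restraint TSV I/O: columns site_a, site_b, cutoff; sites are residue
# numbers, with the keyword "NT" for the N-terminal amine.
# ---------------------------------------------------------------------------

def read_restraints_tsv(path: str | Path,
                        default_cutoff: float = 20.0) -> list[CrosslinkRestraint]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("site_a", "a"):
            continue
        cutoff = float(parts[2]) if len(parts) > 2 else default_cutoff
        out.append(CrosslinkRestraint.of(parts[0], parts[1], cutoff))
    return out


def write_restraints_tsv(restraints: list[CrosslinkRestraint],
                         path: str | Path) -> Path:
    path = Path(path)
    lines = ["site_a\tsite_b\tcutoff"]
    lines += [f"{r.site_a}\t{r.site_b}\t{r.cutoff:g}" for r in restraints]
    path.write_text("\n".join(lines) + "\n")
    return path
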