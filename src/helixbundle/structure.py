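"""Coordinate data model and PDB I/O.

A :class:`Structure` is an ordered list of residues, each an ordered list of
atoms; an :class:`Ensemble` is a list of frames sharing residue topology
(one frame per ``MODEL`` record of a multi-model PDB file).  Conventions:

* residue numbering is 1-based with inclusive ranges; insertion codes are
  not supported;
* a single chain is assumed (apolipoprotein A-I is monomeric here);
  multi-chain files emit a warning and use the first chain;
* alternate locations resolve to the highest-occupancy conformer
  (ties broken by file order);
* hydrogens are parsed but excluded by default from every metric;
* ``HETATM`` records are ignored except selenomethionine (MSE), mapped
  to MET.

File parsing and writing are delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    EnsembleConsistencyError,
    InputError,
    SelectionError,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "Structure",
    "Ensemble",
    "HelixSegmentation",
    "Segment",
    "AtomSelection",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "count_residues_by_class",
    "HYDROPHOBIC_RESIDUES",
]

#: The eight hydrophobic residue types used for surface-area accounting
#: (Ala, Leu, Val, Ile, Pro, Phe, Met, Trp).
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "LEU", "VAL", "ILE", "PRO", "PHE", "MET", "TRP"}
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class AtomRecord:
    """A single atom: name, element, Cartesian coordinates in Å."""

    serial: int
    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InputError(f"atom {self.atom_name!r}: coords must be a finite 3-vector")
        if not self.atom_name:
            raise InputError("atom_name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class ResidueRecord:
    """One residue: 1-based sequence index, 3-letter code, ordered atoms."""

    index: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(self.index, self.name, [a.copy() for a in self.atoms])


class Structure:
    """A single conformation: an ordered list of residues with a label."""

    def __init__(self, residues: Sequence[ResidueRecord], label: str = ""):
        residues = list(residues)
        if not residues:
            raise EmptyStructureError("a Structure needs at least one residue")
        idx = [r.index for r in residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InputError("residue indices must be strictly increasing")
        for r in residues:
            names = [a.atom_name for a in r.atoms]
            if len(names) != len(set(names)):
                raise InputError(f"residue {r.index}: duplicate atom names")
        self.residues = residues
        self.label = label
        self._by_index = {r.index: r for r in residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def residue(self, index: int) -> ResidueRecord:
        try:
            return self._by_index[index]
        except KeyError:
            raise SelectionError(f"no residue with index {index}") from None

    def has_residue(self, index: int) -> bool:
        return index in self._by_index

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self, heavy_only: bool = False) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                out.append(a)
        return out

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        ats = self.atoms(heavy_only=heavy_only)
        return np.array([a.coords for a in ats], dtype=float)

    def set_coords(self, coords: np.ndarray, heavy_only: bool = False) -> None:
        ats = self.atoms(heavy_only=heavy_only)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(ats), 3):
            raise InputError("coordinate array shape mismatch")
        for a, c in zip(ats, coords):
            a.coords = c.copy()

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new = self.copy()
        for a in new.atoms():
            a.coords = rotation @ a.coords + translation
        return new

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], label=self.label)

    def topology_key(self) -> tuple:
        return tuple((r.index, r.name, frozenset(a.atom_name for a in r.atoms))
                     for r in self.residues)

    def __repr__(self) -> str:
        return f"<Structure {self.label!r}: {len(self)} residues>"


class Ensemble:
    """Ordered frames with identical residue topology, optional times (ps)."""

    def __init__(self, frames: Sequence[Structure],
                 times_ps: Sequence[float] | None = None):
        frames = list(frames)
        if not frames:
            raise EmptyStructureError("an Ensemble needs at least one frame")
        key0 = frames[0].topology_key()
        for i, f in enumerate(frames[1:], start=1):
            if f.topology_key() != key0:
                raise EnsembleConsistencyError(
                    f"frame {i} does not share residue topology with frame 0")
        if times_ps is not None:
            times_ps = [float(t) for t in times_ps]
            if len(times_ps) != len(frames):
                raise EnsembleConsistencyError("times_ps length != frame count")
            if any(b <= a for a, b in zip(times_ps, times_ps[1:])):
                raise EnsembleConsistencyError("times_ps must be strictly increasing")
        self.frames = frames
        self.times_ps = times_ps

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]

    @classmethod
    def single(cls, structure: Structure) -> "Ensemble":
        return cls([structure])


@dataclass(frozen=True)
class Segment:
    label: str
    start: int
    end: int
    kind: Literal["helix", "loop"] = "helix"

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(f"segment {self.label}: start > end")

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end


class HelixSegmentation:
    """Labelled residue ranges; residues not covered are implicitly loop."""

    def __init__(self, segments: Iterable[Segment | tuple]):
        segs = [s if isinstance(s, Segment) else Segment(*s) for s in segments]
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise InputError(f"segments {a.label} and {b.label} overlap")
        self.segments = segs

    def helices(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "helix"]

    def segment_of(self, index: int) -> Segment | None:
        for s in self.segments:
            if index in s:
                return s
        return None

    def helix_of(self, index: int) -> str | None:
        """Label of the helix containing `index`, or None (loop)."""
        s = self.segment_of(index)
        return s.label if s is not None and s.kind == "helix" else None

    @classmethod
    def from_dict(cls, spec: dict) -> "HelixSegmentation":
        return cls(Segment(d["label"], int(d["start"]), int(d["end"]),
                           d.get("kind", "helix"))
                   for d in spec["segments"])

    def to_dict(self) -> dict:
        return {"segments": [
            {"label": s.label, "start": s.start, "end": s.end, "kind": s.kind}
            for s in self.segments]}


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _convert_model(model: gemmi.Model, label: str) -> Structure:
    if len(model) == 0:
        raise EmptyStructureError(f"{label}: no ATOM records")
    if len(model) > 1:
        warnings.warn(
            f"{label}: {len(model)} chains found; using the first chain only",
            stacklevel=3)
    chain = model[0]
    residues: list[ResidueRecord] = []
    serial = 0
    for res in chain:
        name = res.name
        if res.het_flag == "H" and name != "MSE":
            continue
        if name == "MSE":
            name = "MET"
        # altloc resolution: highest occupancy wins, ties -> first seen
        best: dict[str, AtomRecord] = {}
        for at in res:
            serial += 1
            rec = AtomRecord(
                serial=at.serial or serial,
                atom_name=at.name,
                element=at.element.name,
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                occupancy=at.occ,
                b_factor=at.b_iso,
            )
            prev = best.get(at.name)
            if prev is None or rec.occupancy > prev.occupancy:
                best[at.name] = rec
        if best:
            residues.append(ResidueRecord(res.seqid.num, name, list(best.values())))
    if not residues:
        raise EmptyStructureError(f"{label}: no ATOM records")
    return Structure(residues, label=label)


def read_pdb(path: str | Path) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble` (one frame per MODEL).

    A file without MODEL records yields a single frame.  Raises
    :class:`InputError` for unreadable files, :class:`EmptyStructureError`
    when no ATOM records are present, and
    :class:`EnsembleConsistencyError` when MODELs disagree on topology.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    frames = [_convert_model(m, label=f"{path.stem}[{i}]" if len(st) > 1 else path.stem)
              for i, m in enumerate(st)]
    return Ensemble(frames)


def write_pdb(ensemble: Ensemble | Structure, path: str | Path) -> Path:
    """Write an ensemble (or single structure) as a standard PDB file.

    Multi-frame ensembles produce MODEL/ENDMDL blocks; a read/write
    round-trip preserves coordinates to 0.001 Å and topology exactly.
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble.single(ensemble)
    path = Path(path)
    st = gemmi.Structure()
    st.name = ensemble.frames[0].label or "model"
    for i, frame in enumerate(ensemble.frames, start=1):
        model = gemmi.Model(i)
        chain = gemmi.Chain("A")
        for res in frame.residues:
            g = gemmi.Residue()
            g.name = res.name
            g.seqid = gemmi.SeqId(res.index, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    try:
        doc = st.make_pdb_string()
        path.write_text(doc)
    except OSError as exc:
        raise InputError(f"cannot write PDB file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Selections and counting
# ---------------------------------------------------------------------------

@dataclass
class AtomSelection:
    """Residue range + atom-name set + heavy-only flag.

    ``atom_names=None`` selects every atom of a residue; ``start``/``end``
    default to the whole structure.  ``strict`` raises when nothing matches.
    """

    start: int | None = None
    end: int | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = True
    strict: bool = False

    def __post_init__(self):
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)


@dataclass
class SelectionResult:
    atoms: list[AtomRecord]
    n_missing: int  # requested atom names absent from in-range residues


def select_atoms(structure: Structure, selection: AtomSelection) -> SelectionResult:
    """Select atoms in residue order; missing requested atoms are skipped
    silently but counted in ``n_missing``."""
    lo = selection.start if selection.start is not None else -np.inf
    hi = selection.end if selection.end is not None else np.inf
    out: list[AtomRecord] = []
    missing = 0
    for res in structure.residues:
        if not (lo <= res.index <= hi):
            continue
        if selection.atom_names is None:
            pool = res.atoms
        else:
            pool = []
            for name in sorted(selection.atom_names):
                a = res.atom(name)
                if a is None:
                    missing += 1
                else:
                    pool.append(a)
        for a in pool:
            if selection.heavy_only and a.is_hydrogen:
                continue
            out.append(a)
    if selection.strict and not out:
        raise SelectionError("selection matched no atoms")
    return SelectionResult(out, missing)


def count_residues_by_class(structure: Structure,
                            residue_names: Iterable[str]) -> int:
    """Number of residues whose 3-letter code is in ``residue_names``."""
    names = {n.upper() for n in residue_names}
    return sum(1 for r in structure.residues if r.name.upper() in names)
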