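"""Three-state secondary-structure assignment (H/E/C).

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
model: with the amide H imputed from the preceding residue's C=O
geometry, the N-H···O=C energy is

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol

and a bond exists when E < −0.5 kcal/mol.  Helix (H) follows the n-turn
rule — residues i..i+3 are helical when i→i+4 turns start at both i−1
and i — with 3₁₀ (i→i+3) and π (i→i+5) turns folded into H.  Strand (E)
comes from parallel/antiparallel bridge patterns; everything else is
coil (C).  Chain termini default to coil when H-bond partners are
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AssignmentError, ComparisonError
from .structure import Structure

__all__ = ["SSAssignment", "assign_ss", "helix_content", "compare_ss_maps"]

_Q1Q2F = 0.084 * 332.0
_HB_CUTOFF = -0.5
_MIN_DIST = 0.5  # guard against degenerate geometry


@dataclass
class SSAssignment:
    """Per-residue H/E/C labels plus the assigner's provenance."""

    per_residue: list[str]
    residue_indices: list[int]
    source: str = "kabsch-sander(-0.5 kcal/mol)"

    def __post_init__(self):
        bad = set(self.per_residue) - {"H", "E", "C"}
        if bad:
            raise AssignmentError(f"invalid labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.per_residue)

    def __str__(self) -> str:
        return "".join(self.per_residue)

    def to_rows(self) -> list[tuple[int, str]]:
        return list(zip(self.residue_indices, self.per_residue))


def _hbond_energy(o: np.ndarray, c: np.ndarray, n: np.ndarray,
                  h: np.ndarray) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return 0.0
    return _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss(structure: Structure) -> SSAssignment:
    """Assign H/E/C per residue from backbone H-bond patterns.

    Requires backbone N, CA, C, O; residues missing any of them are
    reported in an :class:`AssignmentError` (a missing O on the final
    residue is tolerated and that residue is labelled C).
    """
    res = structure.residues
    n_res = len(res)
    missing = []
    bb = {}
    for i, r in enumerate(res):
        atoms = {}
        for name in ("N", "CA", "C", "O"):
            a = r.atom(name)
            if a is None:
                if name == "O" and i == n_res - 1:
                    continue
                missing.append(r.index)
                break
            atoms[name] = a.coords
        else:
            bb[i] = atoms
    if missing:
        raise AssignmentError(
            f"residues missing backbone atoms: {sorted(set(missing))}")

    # imputed amide H: 1.0 Å from N along the preceding C->O direction
    # reversed; the first residue (free amine) has no H-bond donor here
    h_pos: dict[int, np.ndarray] = {}
    for i in range(1, n_res):
        if i in bb and (i - 1) in bb and "O" in bb[i - 1]:
            d = bb[i - 1]["C"] - bb[i - 1]["O"]
            h_pos[i] = bb[i]["N"] + d / np.linalg.norm(d)

    def hbond(i: int, j: int) -> bool:
        """True when CO(i) accepts the NH of residue j."""
        if res[j].name == "PRO":
            return False
        if i not in bb or j not in bb or "O" not in bb[i] or j not in h_pos:
            return False
        e = _hbond_energy(bb[i]["O"], bb[i]["C"], bb[j]["N"], h_pos[j])
        return e < _HB_CUTOFF

    turn = {3: set(), 4: set(), 5: set()}
    for n_turn in (3, 4, 5):
        for i in range(n_res - n_turn):
            if hbond(i, i + n_turn):
                turn[n_turn].add(i)

    labels = ["C"] * n_res
    for n_turn in (4, 3, 5):  # α first; 3₁₀ and π folded into H
        span = 3 if n_turn == 4 else (2 if n_turn == 3 else 4)
        for i in range(1, n_res - n_turn):
            if i in turn[n_turn] and (i - 1) in turn[n_turn]:
                for k in range(i, i + span + 1):
                    labels[k] = "H"

    # bridges / ladders -> E
    def bridge(i: int, j: int) -> bool:
        if abs(i - j) < 3:
            return False
        para = (hbond(i - 1, j) and hbond(j, i + 1)) or \
               (hbond(j - 1, i) and hbond(i, j + 1))
        anti = (hbond(i, j) and hbond(j, i)) or \
               (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
        return para or anti

    strand = set()
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            if bridge(i, j):
                strand.add(i)
                strand.add(j)
    for i in strand:
        if labels[i] != "H":
            labels[i] = "E"

    return SSAssignment(labels, [r.index for r in res])


def helix_content(assignment: SSAssignment) -> float:
    """Percent of residues labelled H (0–100)."""
    if len(assignment) == 0:
        raise AssignmentError("empty assignment")
    return 100.0 * assignment.per_residue.count("H") / len(assignment)


def compare_ss_maps(a: SSAssignment, b: SSAssignment
                    ) -> tuple[float, list[tuple[int, int, str, str]]]:
    """Positional agreement of two assignments of equal length.

    Returns (fraction of identical positions, list of differing segments
    as (start, end, label_a, label_b) in a's residue numbering).
    """
    if len(a) != len(b):
        raise ComparisonError(
            f"length mismatch: {len(a)} vs {len(b)} (provide a mapping)")
    same = sum(x == y for x, y in zip(a.per_residue, b.per_residue))
    diffs = []
    i = 0
    n = len(a)
    while i < n:
        if a.per_residue[i] != b.per_residue[i]:
            j = i
            while (j + 1 < n and a.per_residue[j + 1] != b.per_residue[j + 1]
                   and a.per_residue[j + 1] == a.per_residue[i]
                   and b.per_residue[j + 1] == b.per_residue[i]):
                j += 1
            diffs.append((a.residue_indices[i], a.residue_indices[j],
                          a.per_residue[i], b.per_residue[i]))
            i = j + 1
        else:
            i += 1
    return same / n, diffs
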