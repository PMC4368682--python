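"""Solvent-accessible surface area and amphipathic-helix analysis.

SASA uses Shrake–Rupley sphere sampling: test points on each atom's
solvent-expanded sphere are rejected when inside any neighbour's expanded
sphere; the accessible fraction times the expanded-sphere area is the
atom's SASA.  Default 960 points per atom (deterministic golden-spiral
layout), 1.4 Å probe, hydrogens excluded.  Van der Waals radii: C 1.7,
N 1.55, O 1.52, S 1.8 Å (1.7 Å for anything else).

Helical-wheel analysis places residue i at angle 100°·(i − start) on a
wheel (18 residues close exactly five turns), scores it with a
hydrophobicity scale (Kyte–Doolittle by default) and locates the
hydrophobic face as the arc of maximal summed hydrophobicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError, SequenceError
from .structure import (
    Ensemble,
    HYDROPHOBIC_RESIDUES,
    ONE_TO_THREE,
    Structure,
)

__all__ = [
    "SasaResult",
    "WheelProjection",
    "shrake_rupley_sasa",
    "hydrophobic_mean_sasa",
    "helical_wheel",
    "hydrophobic_face",
    "KYTE_DOOLITTLE",
    "VDW_RADII",
]

#: Kyte–Doolittle hydropathy index (one-letter residue code -> value).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_DEFAULT_RADIUS = 1.70


def sphere_points(n: int) -> np.ndarray:
    """`n` near-uniform unit-sphere points (deterministic golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible areas (Å²)."""

    per_atom: np.ndarray
    per_residue: np.ndarray
    residue_indices: list[int]
    residue_names: list[str]
    probe_radius: float
    n_sphere_points: int
    radii_set: str = "vdw-default"

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def to_rows(self) -> list[tuple[int, str, float]]:
        return [(i, n, float(a)) for i, n, a in
                zip(self.residue_indices, self.residue_names, self.per_residue)]


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area, hydrogens excluded."""
    if probe < 0:
        raise ParameterError("probe radius must be >= 0")
    if n_points < 16:
        raise ParameterError("n_points must be >= 16")
    atoms = []
    atom_residue = []
    for ri, res in enumerate(structure.residues):
        for a in res.heavy_atoms():
            atoms.append(a)
            atom_residue.append(ri)
    if not atoms:
        raise InputError("structure has no heavy atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS)
                      for a in atoms]) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.zeros(len(atoms))
    neighbour_lists = tree.query_ball_point(coords, r=2.0 * rmax)
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        nbrs = [j for j in neighbour_lists[i] if j != i]
        if nbrs:
            nb_xyz = coords[nbrs]
            nb_r = radii[nbrs]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points
    n_res = len(structure.residues)
    per_residue = np.zeros(n_res)
    for area, ri in zip(per_atom, atom_residue):
        per_residue[ri] += area
    return SasaResult(per_atom, per_residue,
                      [r.index for r in structure.residues],
                      [r.name for r in structure.residues],
                      probe, n_points)


def hydrophobic_mean_sasa(ensemble: Ensemble | Structure,
                          hydrophobic_set=HYDROPHOBIC_RESIDUES,
                          probe: float = 1.4, n_points: int = 960) -> float:
    """Mean accessible area per hydrophobic residue (Å²).

    Per frame: (sum of SASA over residues in the set) / (count of residues
    in the set); for an ensemble the per-frame means are averaged.
    """
    names = {n.upper() for n in hydrophobic_set}
    if not names:
        raise ParameterError("hydrophobic set must be non-empty")
    if isinstance(ensemble, Structure):
        ensemble = Ensemble.single(ensemble)
    means = []
    for frame in ensemble:
        result = shrake_rupley_sasa(frame, probe=probe, n_points=n_points)
        mask = np.array([n in names for n in result.residue_names])
        count = int(mask.sum())
        if count == 0:
            means.append(0.0)
        else:
            means.append(float(result.per_residue[mask].sum()) / count)
    return float(np.mean(means))


@dataclass
class WheelProjection:
    """A helical-wheel projection of one segment."""

    sequence: str
    start_index: int
    per_residue_angle: np.ndarray       # degrees in [0, 360)
    per_residue_hydrophobicity: np.ndarray
    moment: np.ndarray = field(init=False)

    def __post_init__(self):
        theta = np.radians(self.per_residue_angle)
        h = self.per_residue_hydrophobicity
        self.moment = np.array([float(np.sum(h * np.cos(theta))),
                                float(np.sum(h * np.sin(theta)))])

    @property
    def moment_magnitude(self) -> float:
        return float(np.linalg.norm(self.moment))

    @property
    def moment_angle(self) -> float:
        return float(np.degrees(np.arctan2(self.moment[1], self.moment[0])) % 360.0)

    def to_rows(self) -> list[tuple[int, float, float]]:
        return [(self.start_index + i, float(a), float(h)) for i, (a, h) in
                enumerate(zip(self.per_residue_angle,
                              self.per_residue_hydrophobicity))]


def helical_wheel(sequence: str, start_index: int = 1,
                  scale: dict[str, float] | None = None,
                  degrees_per_residue: float = 100.0) -> WheelProjection:
    """Project a helix segment onto the 100°-per-residue wheel.

    Residue i sits at angle (i − start) × 100° mod 360°; the hydrophobic
    moment is the vector sum of the per-residue hydrophobicities at their
    wheel angles.
    """
    if len(sequence) < 3:
        raise SequenceError("wheel needs a segment of length >= 3")
    scale = scale or KYTE_DOOLITTLE
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise SequenceError(f"unknown residue letter(s): {sorted(set(bad))}")
    angles = (np.arange(len(sequence)) * degrees_per_residue) % 360.0
    h = np.array([scale[c] for c in sequence], dtype=float)
    return WheelProjection(sequence, start_index, angles, h)


def hydrophobic_face(wheel: WheelProjection, arc_width: float = 120.0
                     ) -> tuple[tuple[float, float], float]:
    """The wheel arc of width `arc_width` maximizing summed hydrophobicity.

    Returns ((arc start°, arc end°), mean hydrophobicity of residues in
    the arc).  The scan is an exhaustive 1° sweep of arc centres; ties
    break deterministically to the smallest centre angle (uniform
    segments therefore report the arc centred at 0°).
    """
    if not 0.0 < arc_width < 360.0:
        raise ParameterError("arc_width must be in (0, 360)")
    best_centre = 0.0
    best_sum = -np.inf
    angles = wheel.per_residue_angle
    h = wheel.per_residue_hydrophobicity
    half = arc_width / 2.0
    for centre in range(360):
        delta = np.abs((angles - centre + 180.0) % 360.0 - 180.0)
        total = float(h[delta <= half].sum())
        if total > best_sum + 1e-12:
            best_sum = total
            best_centre = float(centre)
    delta = np.abs((angles - best_centre + 180.0) % 360.0 - 180.0)
    members = delta <= half
    mean_h = float(h[members].mean()) if members.any() else 0.0
    return ((best_centre - half) % 360.0, (best_centre + half) % 360.0), mean_h
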