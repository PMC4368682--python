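"""Superposition, RMSD protocols, residue-pair distances, helix-axis fits.

RMSD is computed on heavy atoms with no mass weighting.  Residue "sites"
follow the cross-linking conventions of the analysis: Lys resolves to its
Cβ, the N-terminal amine site ("NT", residue 1) to the backbone N, and
any other residue to Cα unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, EnsembleConsistencyError, SelectionError
from .structure import AtomSelection, Ensemble, Structure, select_atoms

__all__ = [
    "Superposition",
    "DistanceSeries",
    "Site",
    "kabsch_superpose",
    "rmsd_series",
    "pair_distance",
    "distance_series",
    "fit_helix_axis",
    "HelixAxisFit",
]


@dataclass
class Superposition:
    """Optimal rigid transform (x -> R x + t) and the minimal RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal superposition of `mobile` onto `reference`.

    Kabsch SVD algorithm with reflection (det = -1) sign correction.
    Requires >= 3 non-collinear point pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateInputError("coordinate sets must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the point cloud itself
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise DegenerateInputError("points are collinear (or coincident)")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(R, t, rmsd)


@dataclass
class DistanceSeries:
    """Per-frame distances (Å) between two residue sites."""

    site_a: "Site"
    site_b: "Site"
    values: np.ndarray
    times_ps: list[float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise SelectionError("distances must be non-negative")

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def to_rows(self) -> list[tuple]:
        times = self.times_ps or [float("nan")] * len(self.values)
        return [(i, t, v) for i, (t, v) in enumerate(zip(times, self.values))]


@dataclass(frozen=True)
class Site:
    """A residue site: index plus the atom rule used to locate it.

    ``atom=None`` applies the default rule (Lys -> CB, residue 1 when the
    site was written "NT" -> backbone N, otherwise CA).
    """

    index: int
    atom: str | None = None
    is_n_terminus: bool = False

    @classmethod
    def parse(cls, token: str | int) -> "Site":
        if isinstance(token, int):
            return cls(token)
        tok = str(token).strip()
        if tok.upper() in ("NT", "NT1", "N-TERM"):
            return cls(1, atom="N", is_n_terminus=True)
        if ":" in tok:
            num, atom = tok.split(":", 1)
            return cls(int(num), atom=atom.strip().upper() or None)
        return cls(int(tok))

    def resolve(self, structure: Structure, strict: bool = True) -> np.ndarray:
        res = structure.residue(self.index)
        name = self.atom
        if name is None:
            name = "CB" if res.name == "LYS" else "CA"
        atom = res.atom(name)
        if atom is None and name == "CB":
            atom = res.atom("CA")  # CA fallback (Gly has no CB)
        if atom is None:
            if strict:
                raise SelectionError(
                    f"site {self.index}:{name} not resolvable in {structure.label!r}")
            return None  # type: ignore[return-value]
        return atom.coords

    def __str__(self) -> str:
        if self.is_n_terminus:
            return "NT"
        return f"{self.index}" if self.atom is None else f"{self.index}:{self.atom}"


def pair_distance(structure: Structure, site_a: Site | int | str,
                  site_b: Site | int | str) -> float:
    """Euclidean distance (Å) between two residue sites; symmetric."""
    a = site_a if isinstance(site_a, Site) else Site.parse(site_a)
    b = site_b if isinstance(site_b, Site) else Site.parse(site_b)
    return float(np.linalg.norm(a.resolve(structure) - b.resolve(structure)))


def distance_series(ensemble: Ensemble, site_a: Site | int | str,
                    site_b: Site | int | str) -> DistanceSeries:
    """Per-frame :func:`pair_distance` with min/max/mean summary attached."""
    a = site_a if isinstance(site_a, Site) else Site.parse(site_a)
    b = site_b if isinstance(site_b, Site) else Site.parse(site_b)
    vals = [pair_distance(f, a, b) for f in ensemble]
    return DistanceSeries(a, b, np.array(vals), times_ps=ensemble.times_ps)


def rmsd_series(ensemble: Ensemble,
                align: AtomSelection | None = None,
                measure: AtomSelection | None = None,
                reference: int = 0) -> DistanceSeries:
    """Per-frame RMSD after aligning `align` atoms onto the reference frame.

    The alignment and measurement selections may differ, reproducing the
    region-aligned protocol (e.g. align on the central helices, measure a
    terminal region).  Defaults: all heavy atoms for both.
    """
    align = align or AtomSelection()
    measure = measure or AtomSelection()
    ref = ensemble[reference]
    ref_align = np.array([a.coords for a in select_atoms(ref, align).atoms])
    ref_measure = np.array([a.coords for a in select_atoms(ref, measure).atoms])
    if ref_align.size == 0 or ref_measure.size == 0:
        raise SelectionError("empty align or measure selection")
    values = []
    for frame in ensemble:
        mob_align = np.array([a.coords for a in select_atoms(frame, align).atoms])
        mob_measure = np.array([a.coords for a in select_atoms(frame, measure).atoms])
        if mob_align.shape != ref_align.shape or mob_measure.shape != ref_measure.shape:
            raise EnsembleConsistencyError("selection size differs across frames")
        sup = kabsch_superpose(mob_align, ref_align)
        moved = sup.apply(mob_measure)
        diff = moved - ref_measure
        values.append(float(np.sqrt((diff ** 2).sum() / len(diff))))
    site = Site(reference, atom="*")
    return DistanceSeries(site, site, np.array(values), times_ps=ensemble.times_ps)


@dataclass
class HelixAxisFit:
    """A fitted helix axis: unit direction, a point on the axis, and the
    per-residue rise (Å) and twist (degrees) measured from consecutive Cα."""

    direction: np.ndarray
    origin: np.ndarray
    rise_per_residue: float
    twist_per_residue: float
    residues_per_turn: float = field(init=False)

    def __post_init__(self):
        self.residues_per_turn = 360.0 / abs(self.twist_per_residue)


def fit_helix_axis(structure: Structure, start: int | None = None,
                   end: int | None = None) -> HelixAxisFit:
    """Fit a helix axis through the Cα trace of a (sub)structure.

    The axis direction is the leading principal component of the Cα cloud,
    oriented along increasing residue index; rise and twist are means over
    consecutive residues of the axial advance and azimuthal advance.
    """
    sel = AtomSelection(start=start, end=end, atom_names=frozenset({"CA"}))
    ca = np.array([a.coords for a in select_atoms(structure, sel).atoms])
    if len(ca) < 4:
        raise DegenerateInputError("axis fit needs at least 4 Cα atoms")
    centroid = ca.mean(axis=0)
    X = ca - centroid
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    axis = Vt[0]
    proj = X @ axis
    if proj[-1] < proj[0]:
        axis = -axis
        proj = -proj
    radial = X - np.outer(proj, axis)
    # orthonormal frame perpendicular to the axis
    u = radial[0] / np.linalg.norm(radial[0])
    v = np.cross(axis, u)
    ang = np.unwrap(np.arctan2(radial @ v, radial @ u))
    rise = float(np.mean(np.diff(proj)))
    twist = float(np.degrees(np.mean(np.diff(ang))))
    return HelixAxisFit(direction=axis, origin=centroid,
                        rise_per_residue=rise, twist_per_residue=twist)
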