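"""Separation direction, rigid-body separation and dataset pruning filters.

The unbinding direction of a complex is estimated from its interface: every
cross-partner atom pair closer than a cutoff (default 5 Å) contributes the
vector joining its atoms, and the separation axis is the normalized mean of
those vectors, oriented from partner A toward partner B.  Partner B is then
translated rigidly along the axis to build a straight-line separation
trajectory (0–10 Å by default).

Three filters remove complexes for which a straight-line rigid separation is
geometrically meaningless:

* the 1-Å overlap test — after a 1 Å separation, more than 80 % of the
  interface pair distances must have increased (otherwise the partners slide
  over each other instead of separating);
* the 10-Å clash test — at 10 Å separation no cross-partner atom pair may
  remain closer than 4 Å (interlocked geometries);
* the slope filter — the mean interface-pair distance, fit linearly against
  the imposed separation, must have slope >= 0.8 (ideal separation gives 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateDirectionError, NoInterfaceError
from .structures import Atom, ComplexStructure, PartnerStructure

#: Contact cutoff for interface atom pairs, Å (pairs require d_ij < cutoff).
PAIR_CUTOFF = 5.0
#: Clash threshold applied at 10 Å separation, Å.
CLASH_CUTOFF = 4.0
#: Minimum fraction of pair distances that must grow after 1 Å separation.
OVERLAP_FRACTION = 0.80
#: Minimum admissible slope of mean pair distance vs imposed separation.
SLOPE_THRESHOLD = 0.8


@dataclass(frozen=True)
class AtomPair:
    """A cross-partner contact pair: atom_i in A, atom_j in B, U_ij = r_j - r_i."""

    atom_i: Atom
    atom_j: Atom
    vector_u: tuple[float, float, float]
    distance: float

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.vector_u) - self.distance) > 1e-9:
            raise ValueError("pair distance inconsistent with its vector")


@dataclass(frozen=True)
class SeparationAxis:
    """Unit separation direction with the raw (unnormalized) mean pair vector."""

    direction: tuple[float, float, float]
    raw_vector: tuple[float, float, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")

    @property
    def unit(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass
class SeparationConfiguration:
    """The complex with partner B rigidly translated by ``distance`` Å."""

    distance: float
    complex: ComplexStructure


def find_interface_pairs(
    complex_: ComplexStructure,
    cutoff: float = PAIR_CUTOFF,
    include_hydrogens: bool = True,
) -> list[AtomPair]:
    """All cross-partner atom pairs with distance strictly below ``cutoff``.

    Pairs are ordered by (serial of the A atom, serial of the B atom) so
    downstream sums are deterministic.  Raises :class:`NoInterfaceError`
    when no pair qualifies.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")

    def keep(atom: Atom) -> bool:
        return include_hydrogens or not atom.name.upper().startswith("H")

    atoms_a = [a for a in complex_.partner_a.atoms if keep(a)]
    atoms_b = [b for b in complex_.partner_b.atoms if keep(b)]
    if not atoms_a or not atoms_b:
        raise NoInterfaceError(f"{complex_.name}: no atoms eligible for pairing")
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    tree_b = cKDTree(xb)
    pairs: list[AtomPair] = []
    for ia, ja_list in enumerate(cKDTree(xa).query_ball_tree(tree_b, cutoff)):
        for jb in sorted(ja_list, key=lambda j: atoms_b[j].serial):
            u = xb[jb] - xa[ia]
            d = float(np.linalg.norm(u))
            if d < cutoff:  # strict: pairs at exactly the cutoff are excluded
                pairs.append(AtomPair(atoms_a[ia], atoms_b[jb], tuple(u), d))
    pairs.sort(key=lambda p: (p.atom_i.serial, p.atom_j.serial))
    if not pairs:
        raise NoInterfaceError(
            f"{complex_.name}: no cross-partner atom pair within {cutoff} Å"
        )
    return pairs


def separation_direction(pairs: list[AtomPair]) -> SeparationAxis:
    """Mean of the cross-interface pair vectors, normalized, oriented A -> B.

    Raises :class:`DegenerateDirectionError` when the pair vectors cancel
    (fully interlocked interface with no net outward direction).
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    u = np.array([p.vector_u for p in pairs], dtype=float)
    raw = u.mean(axis=0)
    norm = float(np.linalg.norm(raw))
    if norm < 1e-6:
        raise DegenerateDirectionError(
            f"interface pair vectors cancel (|mean| = {norm:.2e} Å)"
        )
    direction = raw / norm
    return SeparationAxis(tuple(direction), tuple(raw), len(pairs))


def orient_axis(complex_: ComplexStructure, axis: SeparationAxis) -> SeparationAxis:
    """Flip the axis if moving B along +direction would not separate the partners."""
    delta = complex_.partner_b.centroid - complex_.partner_a.centroid
    if float(np.dot(axis.unit, delta)) < 0:
        return SeparationAxis(
            tuple(-axis.unit), tuple(-np.asarray(axis.raw_vector)), axis.n_pairs
        )
    return axis


def separate(
    complex_: ComplexStructure, axis: SeparationAxis, distance: float
) -> SeparationConfiguration:
    """Rigidly translate partner B by ``distance`` Å along the axis."""
    if distance < 0:
        raise ValueError("separation distance must be >= 0")
    if distance == 0:
        moved = complex_
    else:
        moved = ComplexStructure(
            complex_.partner_a,
            complex_.partner_b.translated(distance * axis.unit),
            name=complex_.name,
        )
    return SeparationConfiguration(distance, moved)


def generate_separations(
    complex_: ComplexStructure,
    axis: SeparationAxis,
    distances: list[float],
) -> list[SeparationConfiguration]:
    """One rigid-body configuration per requested separation distance."""
    return [separate(complex_, axis, d) for d in distances]


def _pair_distances_at(
    complex_: ComplexStructure, axis: SeparationAxis, pairs: list[AtomPair], d: float
) -> np.ndarray:
    """Distances of the (frozen) bound-state pair list after separating by d."""
    shift = d * axis.unit
    xi = np.array([p.atom_i.coords for p in pairs])
    xj = np.array([p.atom_j.coords for p in pairs]) + shift
    return np.linalg.norm(xj - xi, axis=1)


def prune_overlap_1A(
    complex_: ComplexStructure,
    axis: SeparationAxis,
    pairs: list[AtomPair],
    threshold: float = OVERLAP_FRACTION,
) -> tuple[bool, float]:
    """1-Å overlap test: keep iff > ``threshold`` of pair distances increased.

    Returns ``(keep, fraction_increased)``.
    """
    d0 = np.array([p.distance for p in pairs])
    d1 = _pair_distances_at(complex_, axis, pairs, 1.0)
    fraction = float(np.mean(d1 > d0))
    return fraction > threshold, fraction


def prune_clash_10A(
    complex_: ComplexStructure,
    axis: SeparationAxis,
    clash_cutoff: float = CLASH_CUTOFF,
    separation: float = 10.0,
) -> tuple[bool, float]:
    """10-Å clash test: reject iff any cross pair is closer than ``clash_cutoff``
    once the partners are separated by ``separation`` Å.

    Returns ``(keep, min_cross_distance)``.
    """
    if clash_cutoff <= 0:
        raise ValueError("clash_cutoff must be > 0")
    config = separate(complex_, axis, separation)
    xa = config.complex.partner_a.coords
    xb = config.complex.partner_b.coords
    d_min, _ = cKDTree(xa).query(xb, k=1)
    min_cross = float(np.min(d_min))
    return min_cross >= clash_cutoff, min_cross


def pair_distance_slope(
    complex_: ComplexStructure,
    axis: SeparationAxis,
    pairs: list[AtomPair],
    distances: list[float] | None = None,
) -> float:
    """Least-squares slope of mean interface-pair distance vs imposed separation.

    The pair list is frozen at the bound state; a perfectly detected axis
    gives slope 1, a sliding axis gives a slope well below it.
    """
    if distances is None:
        distances = [float(d) for d in range(11)]
    if len(distances) < 3:
        raise ValueError("need at least 3 separation distances for a slope fit")
    means = [float(np.mean(_pair_distances_at(complex_, axis, pairs, d))) for d in distances]
    slope, _ = np.polyfit(np.asarray(distances, dtype=float), np.asarray(means), 1)
    return float(slope)


def prune_by_slope(slope: float, threshold: float = SLOPE_THRESHOLD) -> bool:
    """Keep iff slope >= threshold (complexes with slope < 0.8 are removed)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return slope >= threshold


@dataclass
class PruningReport:
    """Verdicts of the three geometry filters for one complex."""

    complex_name: str
    n_pairs: int
    fraction_increased: float
    min_cross_distance: float
    slope: float
    keep_overlap: bool
    keep_clash: bool
    keep_slope: bool

    @property
    def keep(self) -> bool:
        return self.keep_overlap and self.keep_clash and self.keep_slope

    @property
    def verdict(self) -> str:
        if self.keep:
            return "keep"
        reasons = []
        if not self.keep_overlap:
            reasons.append("overlap_1A")
        if not self.keep_clash:
            reasons.append("clash_10A")
        if not self.keep_slope:
            reasons.append("slope")
        return "reject:" + "+".join(reasons)


def prune_complex(
    complex_: ComplexStructure,
    axis: SeparationAxis,
    pairs: list[AtomPair],
    overlap_threshold: float = OVERLAP_FRACTION,
    clash_cutoff: float = CLASH_CUTOFF,
    slope_threshold: float = SLOPE_THRESHOLD,
) -> PruningReport:
    """Apply all three filters and collect the verdicts."""
    keep_overlap, fraction = prune_overlap_1A(complex_, axis, pairs, overlap_threshold)
    keep_clash, min_cross = prune_clash_10A(complex_, axis, clash_cutoff)
    slope = pair_distance_slope(complex_, axis, pairs)
    keep_slope = prune_by_slope(slope, slope_threshold)
    return PruningReport(
        complex_.name, len(pairs), fraction, min_cross, slope,
        keep_overlap, keep_clash, keep_slope,
    )
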