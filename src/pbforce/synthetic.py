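"""Synthetic two-partner complexes with controlled geometry and charge.

The analysis depends only on geometry and charge, not chemistry, so test
complexes are built from pseudo-atoms of uniform radius arranged in planar
slabs.  Each partner is two parallel m x m layers of atoms: an *interface*
layer facing the other partner and a *back* layer behind it.  The interface
layers carry the requested interface charge and the back layers absorb the
remainder of the requested net charge, so net and interface polarity can be
dialed independently — including the dipolar combination (same-sign net
charges, opposite-sign interface charges) associated with soft-landing
force profiles.

An interlocked variant threads an arm of partner B through partner A so
that rigid separation leaves clashing cross-partner contacts at 10 Å — the
geometry the 10-Å/4-Å pruning filter exists to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .classify import Category
from .structures import Atom, ComplexStructure, PartnerStructure

#: Pseudo-atom van der Waals radius, Å (carbon-like).
DEFAULT_RADIUS = 1.8
#: Separation between the interface and back layer of one slab, Å.
LAYER_SPACING = 3.0


@dataclass(frozen=True)
class SlabComplexSpec:
    """Recipe for a flat-interface two-slab complex.

    ``gap`` is the bound-state distance between the two interface atom
    layers (atom centers), Å.  ``atoms_per_slab`` must be twice a perfect
    square (two m x m layers per slab).
    """

    atoms_per_slab: int = 32
    slab_extent: float = 9.0
    gap: float = 4.0
    net_charge_a: float = -3.0
    net_charge_b: float = 3.0
    interface_charge_a: float = -2.0
    interface_charge_b: float = 2.0
    interface_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = DEFAULT_RADIUS
    jitter: float = 0.0
    seed: int = 0
    name: str = "slab"
    #: Charge (e) concentrated on the 4 central interface atoms and removed
    #: uniformly from the remaining interface atoms; the interface total is
    #: unchanged.  Same-sign motifs on facing slabs emulate the specific
    #: short-range pairwise interactions that dominate near contact.
    interface_motif_a: float = 0.0
    interface_motif_b: float = 0.0

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if self.atoms_per_slab < 4:
            raise ValueError("atoms_per_slab must be >= 4")
        m = round((self.atoms_per_slab / 2) ** 0.5)
        if 2 * m * m != self.atoms_per_slab:
            raise ValueError("atoms_per_slab must be 2*m^2 for integer m")


@dataclass(frozen=True)
class InterlockSpec:
    """A slab complex plus an arm of B threading through A."""

    base: SlabComplexSpec = field(default_factory=SlabComplexSpec)
    arm_length: float = 16.0
    arm_atoms: int = 6


def _layer(m: int, extent: float, z: float) -> np.ndarray:
    xs = np.linspace(-extent / 2, extent / 2, m)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), np.full(m * m, z)], axis=1)
    return pts


def _rotation_to(normal: Sequence[float]) -> Rotation:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rot, _ = Rotation.align_vectors(n[None, :], np.array([[0.0, 0.0, 1.0]]))
    return rot


def make_slab_complex(spec: SlabComplexSpec) -> ComplexStructure:
    """Build the two-slab complex described by ``spec`` (deterministic per seed)."""
    m = round((spec.atoms_per_slab / 2) ** 0.5)
    n_layer = m * m
    rng = np.random.default_rng(spec.seed)
    rot = _rotation_to(spec.interface_normal)

    def build_partner(label: str, sign: float, iface_q: float, net_q: float,
                      motif_q: float, serial_start: int) -> PartnerStructure:
        # sign = -1 for partner A (below the interface plane), +1 for B.
        z_iface = sign * spec.gap / 2
        z_back = sign * (spec.gap / 2 + LAYER_SPACING)
        iface_xyz = _layer(m, spec.slab_extent, z_iface)
        coords = np.vstack([iface_xyz, _layer(m, spec.slab_extent, z_back)])
        if spec.jitter > 0:
            coords = coords + rng.uniform(-spec.jitter, spec.jitter, coords.shape)
        coords = rot.apply(coords)
        iface_charges = np.full(n_layer, iface_q / n_layer)
        if motif_q != 0.0:
            if n_layer < 5:
                raise ValueError("interface motif needs at least a 3x3 layer")
            lateral = np.linalg.norm(iface_xyz[:, :2], axis=1)
            center = np.argsort(lateral, kind="stable")[:4]
            outer = np.setdiff1d(np.arange(n_layer), center)
            iface_charges[center] += motif_q / 4
            iface_charges[outer] -= motif_q / len(outer)
        charges = np.concatenate([
            iface_charges,
            np.full(n_layer, (net_q - iface_q) / n_layer),
        ])
        atoms = [
            Atom(serial_start + i, label, "C", tuple(coords[i]), float(charges[i]),
                 spec.radius, residue="SLB", res_seq=1 + i // n_layer)
            for i in range(2 * n_layer)
        ]
        return PartnerStructure(label, atoms)

    partner_a = build_partner(
        "A", -1.0, spec.interface_charge_a, spec.net_charge_a,
        spec.interface_motif_a, 1,
    )
    partner_b = build_partner(
        "B", +1.0, spec.interface_charge_b, spec.net_charge_b,
        spec.interface_motif_b, 1 + 2 * n_layer,
    )
    return ComplexStructure(partner_a, partner_b, name=spec.name)


def make_interlocked_complex(spec: InterlockSpec) -> ComplexStructure:
    """Slab complex with an uncharged arm of B threading through partner A.

    The arm starts at B's interface layer and extends through A along the
    inward normal; its tip remains within clash range of A even after a
    10 Å rigid separation, so the complex is rejected by the clash filter.
    """
    base = make_slab_complex(spec.base)
    if spec.arm_atoms == 0:
        return base
    rot = _rotation_to(spec.base.interface_normal)
    lattice = spec.base.slab_extent / (round((spec.base.atoms_per_slab / 2) ** 0.5) - 1)
    z0 = spec.base.gap / 2
    zs = np.linspace(z0, z0 - spec.arm_length, spec.arm_atoms + 1)[1:]
    off = lattice / 2  # thread between the lattice sites of A
    arm_coords = rot.apply(np.stack(
        [np.full_like(zs, off), np.full_like(zs, off), zs], axis=1
    ))
    start = max(a.serial for a in base.atoms) + 1
    arm = [
        Atom(start + i, "B", "C", tuple(arm_coords[i]), 0.0, spec.base.radius,
             residue="ARM", res_seq=99)
        for i in range(len(zs))
    ]
    partner_b = PartnerStructure("B", list(base.partner_b.atoms) + arm)
    return ComplexStructure(base.partner_a, partner_b, name=spec.base.name)


def make_point_pair(
    q1: float, q2: float, d: float, radius: float = DEFAULT_RADIUS,
    name: str = "point_pair",
) -> ComplexStructure:
    """Two single-atom partners on the z axis, d Å apart (solver fixture)."""
    a = Atom(1, "A", "Q1", (0.0, 0.0, 0.0), q1, radius)
    b = Atom(2, "B", "Q2", (0.0, 0.0, float(d)), q2, radius)
    return ComplexStructure(
        PartnerStructure("A", [a]), PartnerStructure("B", [b]), name=name
    )


#: Noise-free archetype force profiles (kT/Å) over d = 0..10 Å, one per category.
PROFILE_ARCHETYPES: dict[Category, list[float]] = {
    Category.MAX_AT_DISTANCE: [-2, -3, -5, -3, -2, -1, -0.8, -0.6, -0.4, -0.3, -0.2],
    Category.MAX_AT_BOUND: [-10, -8, -6, -4, -2, -1, -0.8, -0.6, -0.4, -0.3, -0.2],
    Category.SOFT_LANDING: [2, -1, -4, -2, -1, -0.5, -0.4, -0.3, -0.2, -0.15, -0.1],
    Category.REPULSIVE: [3, 2, 1.5, 1, 0.5, 0.2, 0.15, 0.1, 0.08, 0.06, 0.05],
}


def make_profile_fixture(
    category: Category | str, seed: int = 0, noise: float = 0.004
) -> tuple[list[float], list[float]]:
    """Archetype profile of a category plus seeded sub-tolerance noise.

    Returns ``(distances, forces)``.  The default noise amplitude is below
    half the classification tolerance, so the label is guaranteed stable.
    """
    category = Category(category)
    rng = np.random.default_rng(seed)
    base = np.asarray(PROFILE_ARCHETYPES[category], dtype=float)
    f = base + rng.uniform(-noise, noise, base.shape)
    return [float(k) for k in range(11)], [float(v) for v in f]


@dataclass(frozen=True)
class ShippedFixture:
    """A named synthetic complex with its expected pipeline behaviour."""

    spec: SlabComplexSpec | InterlockSpec
    passes_pruning: bool
    expected_category: Category | None  # F_int category under the 2-dielectric model

    def build(self) -> ComplexStructure:
        if isinstance(self.spec, InterlockSpec):
            return make_interlocked_complex(self.spec)
        return make_slab_complex(self.spec)


def shipped_fixtures() -> dict[str, ShippedFixture]:
    """The stock synthetic complexes exercised by the end-to-end analysis.

    Charge layouts follow the polarity patterns associated with each
    profile category: opposite net charges for bound-state attraction,
    same-sign net charges for repulsion, and the dipolar layout (same-sign
    nets, opposite-sign interfaces) that yields soft landing.  In the
    dipolar fixtures a like-signed charge motif on the facing central
    interface atoms supplies the specific short-range pairwise repulsion
    that turns the bound-state force repulsive (soft landing) or merely
    damps the attraction near contact (maximum attraction at a distance).
    """
    fixtures = {
        "attract_bound": ShippedFixture(
            SlabComplexSpec(
                gap=3.6,  # van der Waals contact: close interface pairs
                net_charge_a=-3.0, net_charge_b=3.0,
                interface_charge_a=-3.0, interface_charge_b=3.0,
                name="attract_bound",
            ),
            passes_pruning=True,
            expected_category=Category.MAX_AT_BOUND,
        ),
        "repulsive_pair": ShippedFixture(
            SlabComplexSpec(
                net_charge_a=3.0, net_charge_b=3.0,
                interface_charge_a=1.0, interface_charge_b=1.0,
                name="repulsive_pair",
            ),
            passes_pruning=True,
            expected_category=Category.REPULSIVE,
        ),
        "dipolar_interface": ShippedFixture(
            SlabComplexSpec(
                net_charge_a=1.0, net_charge_b=1.0,
                interface_charge_a=-3.0, interface_charge_b=3.0,
                interface_motif_a=1.5, interface_motif_b=1.5,
                name="dipolar_interface",
            ),
            passes_pruning=True,
            expected_category=Category.SOFT_LANDING,
        ),
        "distant_attractor": ShippedFixture(
            SlabComplexSpec(
                net_charge_a=-3.0, net_charge_b=3.0,
                interface_charge_a=-2.0, interface_charge_b=2.0,
                interface_motif_a=1.5, interface_motif_b=1.5,
                name="distant_attractor",
            ),
            passes_pruning=True,
            expected_category=Category.MAX_AT_DISTANCE,
        ),
        "interlocked": ShippedFixture(
            InterlockSpec(
                base=SlabComplexSpec(
                    net_charge_a=-3.0, net_charge_b=3.0,
                    interface_charge_a=-2.0, interface_charge_b=2.0,
                    name="interlocked",
                )
            ),
            passes_pruning=False,
            expected_category=None,
        ),
    }
    return fixtures
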