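"""Molecular structures with per-atom charges and radii.

A two-partner complex is represented as two :class:`PartnerStructure`
objects (labelled ``A`` and ``B``), each an ordered list of :class:`Atom`
records carrying coordinates (Å), a partial charge (e) and a van der Waals
radius (Å).  Structures are read from whitespace-delimited (APBS-style) PQR
files, or from PDB files combined with a ``(residue, atom name) ->
(charge, radius)`` parameter table.

Charge bookkeeping — net charge per partner and the charge carried by the
interface atoms of each partner — feeds the polarity cross-tabulation of
the classification report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    ChainCountError,
    ParameterLookupError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

PartnerLabel = Literal["A", "B"]

#: Fallback values assigned in lenient PDB parameterization: a zero charge
#: leaves electrostatics untouched while a mid-size radius keeps the atom
#: in the dielectric cavity.
LENIENT_CHARGE = 0.0
LENIENT_RADIUS = 1.5


@dataclass(frozen=True)
class Atom:
    """One atom: id, partner assignment, name, coords (Å), charge (e), radius (Å)."""

    serial: int
    partner: PartnerLabel
    name: str
    coords: tuple[float, float, float]
    charge: float
    radius: float
    residue: str = "UNK"
    res_seq: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be > 0, got {self.radius}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial}: non-finite coordinates {self.coords}")

    def moved_to(self, coords: Sequence[float]) -> "Atom":
        return replace(self, coords=(float(coords[0]), float(coords[1]), float(coords[2])))


@dataclass
class PartnerStructure:
    """One binding partner: a non-empty, ordered list of atoms sharing a label."""

    label: PartnerLabel
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"partner {self.label}: empty atom list")
        bad = [a.serial for a in self.atoms if a.partner != self.label]
        if bad:
            raise ValueError(
                f"partner {self.label}: atoms {bad[:5]} carry a different partner label"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def translated(self, shift: Sequence[float]) -> "PartnerStructure":
        s = np.asarray(shift, dtype=float)
        return PartnerStructure(
            self.label, [a.moved_to(np.asarray(a.coords) + s) for a in self.atoms]
        )


@dataclass
class ComplexStructure:
    """A two-partner complex (partners A and B)."""

    partner_a: PartnerStructure
    partner_b: PartnerStructure
    name: str = "complex"

    def __post_init__(self) -> None:
        if self.partner_a.label == self.partner_b.label:
            raise ValueError("partner labels must be distinct")

    @property
    def atoms(self) -> list[Atom]:
        """All atoms, partner A first (fixed order for reproducible sums)."""
        return list(self.partner_a.atoms) + list(self.partner_b.atoms)


def net_charge(partner: PartnerStructure) -> float:
    """Total charge of one partner (e), summed in atom order."""
    return float(sum(a.charge for a in partner.atoms))


def interface_charge(complex_: ComplexStructure, pairs: Iterable) -> tuple[float, float]:
    """Charge carried by the distinct interface atoms of each partner (e).

    ``pairs`` is the cross-partner contact-pair list from
    :func:`pbforce.geometry.find_interface_pairs`; an atom taking part in
    several pairs is counted once.  An empty pair list yields ``(0, 0)``
    with a warning.
    """
    pairs = list(pairs)
    if not pairs:
        logger.warning("interface_charge: empty pair list for %s", complex_.name)
        return 0.0, 0.0
    seen_a: dict[int, float] = {}
    seen_b: dict[int, float] = {}
    for p in pairs:
        seen_a.setdefault(p.atom_i.serial, p.atom_i.charge)
        seen_b.setdefault(p.atom_j.serial, p.atom_j.charge)
    return float(sum(seen_a.values())), float(sum(seen_b.values()))


def classify_polarity(qa: float, qb: float, tol: float = 0.01) -> str:
    """Classify a charge pair as ``same``, ``opposite`` or ``zero_on_one``.

    Charges with magnitude <= ``tol`` count as zero; the tolerance separates
    a genuinely uncharged partner from floating-point residue.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    za, zb = abs(qa) <= tol, abs(qb) <= tol
    if za or zb:
        return "zero_on_one"
    return "same" if (qa > 0) == (qb > 0) else "opposite"


# ---------------------------------------------------------------------------
# PQR input / output (whitespace-delimited, APBS dialect)
# ---------------------------------------------------------------------------

def _parse_pqr_line(line: str, lineno: int):
    parts = line.split()
    # ATOM serial name resName [chainID] resSeq x y z charge radius
    if len(parts) == 11:
        (_, serial, name, res, chain, seq, x, y, z, q, r) = parts
    elif len(parts) == 10:
        (_, serial, name, res, seq, x, y, z, q, r) = parts
        chain = ""
    else:
        raise StructureParseError(
            f"expected 10 or 11 whitespace-separated fields, got {len(parts)}", lineno
        )
    try:
        return (
            int(serial), name, res, chain, int(seq),
            float(x), float(y), float(z), float(q), float(r),
        )
    except ValueError as exc:
        raise StructureParseError(f"malformed numeric field ({exc})", lineno) from None


def read_pqr(path: str | Path) -> ComplexStructure:
    """Read a two-chain PQR file into a :class:`ComplexStructure`.

    The first chain encountered becomes partner A, the second partner B.
    Raises :class:`ChainCountError` unless exactly two chain identifiers
    are present, and :class:`StructureParseError` (with the line number)
    on malformed records.
    """
    path = Path(path)
    records: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                records.append(_parse_pqr_line(line, lineno))
    if not records:
        raise StructureParseError("no ATOM records found")
    chains: list[str] = []
    for rec in records:
        if rec[3] not in chains:
            chains.append(rec[3])
    if len(chains) != 2:
        raise ChainCountError(chains)
    by_chain: dict[str, list[Atom]] = {c: [] for c in chains}
    for label, chain in zip("AB", chains):
        for rec in records:
            if rec[3] != chain:
                continue
            serial, name, res, _, seq, x, y, z, q, r = rec
            by_chain[chain].append(
                Atom(serial, label, name, (x, y, z), q, r, residue=res, res_seq=seq)
            )
    return ComplexStructure(
        PartnerStructure("A", by_chain[chains[0]]),
        PartnerStructure("B", by_chain[chains[1]]),
        name=path.stem,
    )


def write_pqr(complex_: ComplexStructure, path: str | Path) -> None:
    """Write a complex as whitespace-delimited PQR (chains A and B)."""
    with open(path, "w") as fh:
        fh.write(f"REMARK written by pbforce: {complex_.name}\n")
        for partner, chain in ((complex_.partner_a, "A"), (complex_.partner_b, "B")):
            for a in partner.atoms:
                x, y, z = a.coords
                fh.write(
                    f"ATOM {a.serial:6d} {a.name:<4s} {a.residue:<4s} {chain} "
                    f"{a.res_seq:4d} {x:10.3f} {y:10.3f} {z:10.3f} "
                    f"{a.charge:8.4f} {a.radius:7.4f}\n"
                )


# ---------------------------------------------------------------------------
# PDB input with a pluggable charge/radius parameter table
# ---------------------------------------------------------------------------

def read_parameter_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Read a tab-separated ``residue  atom  charge  radius`` table."""
    table: dict[tuple[str, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise StructureParseError("expected 4 fields: residue atom charge radius", lineno)
            res, name, q, r = parts
            table[(res.upper(), name.upper())] = (float(q), float(r))
    return table


def read_pdb_with_params(
    path: str | Path,
    params: str | Path | dict[tuple[str, str], tuple[float, float]],
    strict: bool = False,
) -> ComplexStructure:
    """Read a two-chain PDB file, assigning charges/radii from a table.

    Atoms absent from the table get charge 0 e and radius 1.5 Å in lenient
    mode (with a logged warning), or raise :class:`ParameterLookupError`
    when ``strict`` is set.
    """
    import gemmi

    path = Path(path)
    if not isinstance(params, dict):
        params = read_parameter_table(params)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [ch.name for ch in model]
    if len(chains) != 2:
        raise ChainCountError(chains)
    partners = []
    serial = 0
    for label, chain in zip("AB", model):
        atoms: list[Atom] = []
        for residue in chain:
            for at in residue:
                serial += 1
                key = (residue.name.upper(), at.name.upper())
                if key in params:
                    q, r = params[key]
                elif strict:
                    raise ParameterLookupError(
                        f"no parameters for atom {at.name} in residue "
                        f"{residue.name} (chain {chain.name})"
                    )
                else:
                    logger.warning(
                        "no parameters for %s/%s; using charge %.1f, radius %.1f",
                        residue.name, at.name, LENIENT_CHARGE, LENIENT_RADIUS,
                    )
                    q, r = LENIENT_CHARGE, LENIENT_RADIUS
                atoms.append(
                    Atom(
                        serial, label, at.name,
                        (at.pos.x, at.pos.y, at.pos.z), q, r,
                        residue=residue.name, res_seq=residue.seqid.num,
                    )
                )
        partners.append(PartnerStructure(label, atoms))
    return ComplexStructure(partners[0], partners[1], name=path.stem)
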