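"""Structures with per-atom charges and radii, read from PQR or PDB.

PQR is the canonical charged input: its occupancy/B-factor columns carry the
partial charge (elementary charges) and radius (Å) that define both the
electrostatic potential and the molecular surface.  PDB input is a
convenience path — radii are assigned from a bundled table and charges are
set to zero, because protonation and charge assignment are deliberately not
reimplemented here (use a preparation tool such as PDB2PQR and feed the
resulting PQR instead).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "ParseError",
    "EmptyStructureError",
    "parse_pqr",
    "parse_pdb",
    "write_pqr",
    "ELEMENT_RADII",
]


class ParseError(ValueError):
    """A structure file could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """No atoms were found where at least one is required."""


@dataclass(frozen=True)
class Atom:
    """A single atom with position (Å), partial charge (e) and radius (Å)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    charge: float
    radius: float
    insertion_code: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: non-finite position {pos}")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius {self.radius}")
        object.__setattr__(self, "position", pos)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """Residue identity: (chain_id, residue_number, insertion_code)."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered collection of atoms, as read from a PQR or PDB file."""

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of atom coordinates in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def translated(self, shift) -> "Structure":
        """Return a copy rigidly translated by ``shift`` (3-vector, Å)."""
        shift = np.asarray(shift, dtype=float)
        return Structure(
            atoms=[replace(a, position=a.position + shift) for a in self.atoms],
            title=self.title,
        )

    def without_hetero(self) -> "Structure":
        """Copy without HETATM records (waters, ions, ligands)."""
        return Structure(
            atoms=[a for a in self.atoms if not a.hetero], title=self.title
        )


# Per-element fallback radii (Å), Bondi-style van der Waals values.  Used for
# PDB input only; PQR carries its own radii.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.40,
}


def _element_from_name(name: str) -> str | None:
    """Guess the element from a PDB atom name (digits stripped, greedy 2-letter
    match first so CL/BR/ZN resolve before C/B/Z)."""
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        return None
    if stripped[:2] in ELEMENT_RADII and len(stripped) >= 2:
        # Two-letter elements are rare in protein atom names; prefer them only
        # when the one-letter prefix is not itself a common organic element.
        if stripped[0] not in ("C", "N", "O", "H", "S", "P"):
            return stripped[:2]
    if stripped[0] in ELEMENT_RADII:
        return stripped[0]
    if stripped[:2] in ELEMENT_RADII:
        return stripped[:2]
    return None


def parse_pqr(stream: IO[str] | Iterable[str], *, title: str = "") -> Structure:
    """Parse a whitespace-separated PQR file into a :class:`Structure`.

    Both common dialects are accepted and detected per record by token count:
    11 fields include a chain identifier, 10 fields omit it.  Records other
    than ATOM/HETATM are ignored.  Atom order in the file is preserved.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(stream, start=1):
        fields = line.split()
        if not fields or fields[0] not in ("ATOM", "HETATM"):
            continue
        if len(fields) == 11:
            (_, serial, name, res_name, chain, res_seq, x, y, z, q, r) = fields
        elif len(fields) == 10:
            (_, serial, name, res_name, res_seq, x, y, z, q, r) = fields
            chain = ""
        else:
            raise ParseError(
                f"line {lineno}: expected 10 or 11 fields in PQR record, "
                f"got {len(fields)}"
            )
        # Insertion codes show up as a trailing letter on the residue number.
        icode = ""
        if res_seq and res_seq[-1].isalpha():
            res_seq, icode = res_seq[:-1], res_seq[-1]
        try:
            atom = Atom(
                serial=int(serial),
                name=name,
                residue_name=res_name,
                chain_id=chain,
                residue_number=int(res_seq),
                insertion_code=icode,
                position=np.array([float(x), float(y), float(z)]),
                charge=float(q),
                radius=float(r),
                hetero=fields[0] == "HETATM",
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        atoms.append(atom)
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records found in PQR input")
    return Structure(atoms=atoms, title=title)


def write_pqr(structure: Structure, stream: IO[str]) -> None:
    """Write a Structure as whitespace-separated PQR (chain dialect when any
    atom has a chain id)."""
    with_chain = any(a.chain_id for a in structure)
    for a in structure:
        res_seq = f"{a.residue_number}{a.insertion_code}"
        record = "HETATM" if a.hetero else "ATOM"
        fields = [record, str(a.serial), a.name, a.residue_name]
        if with_chain:
            fields.append(a.chain_id or "X")
        fields.append(res_seq)
        fields += [f"{c:.3f}" for c in a.position]
        fields += [f"{a.charge:.4f}", f"{a.radius:.4f}"]
        stream.write(" ".join(fields) + "\n")


def parse_pdb(
    stream: IO[str] | Iterable[str],
    radius_table: Mapping[tuple[str, str], float] | None = None,
    *,
    title: str = "",
) -> Structure:
    """Parse fixed-column PDB ATOM/HETATM records.

    Radii come from ``radius_table`` keyed by (residue_name, atom_name), with
    a per-element fallback from :data:`ELEMENT_RADII`.  Charges are set to 0
    and a warning is logged: potentials and scores computed from uncharged
    input are degenerate.  Only the first alternate location is kept.
    """
    radius_table = radius_table or {}
    atoms: list[Atom] = []
    unknown: list[str] = []
    seen_altloc: set[tuple[str, str, int, str]] = set()
    dropped_altloc = 0
    for lineno, line in enumerate(stream, start=1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {lineno}: PDB record shorter than 54 columns")
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip()
        icode = line[26].strip()
        try:
            serial = int(line[6:11])
            res_seq = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        key = (name, chain, res_seq, icode)
        if altloc:
            if key in seen_altloc:
                dropped_altloc += 1
                continue
            seen_altloc.add(key)
        radius = radius_table.get((res_name, name))
        if radius is None:
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            element = element or _element_from_name(name) or ""
            radius = ELEMENT_RADII.get(element)
        if radius is None:
            unknown.append(f"{res_name} {name} (serial {serial})")
            continue
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                residue_name=res_name,
                chain_id=chain,
                residue_number=res_seq,
                insertion_code=icode,
                position=xyz,
                charge=0.0,
                radius=radius,
                hetero=record == "HETATM",
            )
        )
    if unknown:
        raise ParseError(
            "no radius known for atoms: " + ", ".join(unknown)
        )
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records found in PDB input")
    if dropped_altloc:
        logger.warning("dropped %d alternate-location atoms", dropped_altloc)
    msg = (
        "PDB input carries no partial charges; all charges set to 0. "
        "Potentials and electrostatics scores from this structure are "
        "degenerate — prepare a PQR file for charged calculations."
    )
    logger.warning(msg)
    warnings.warn(msg, stacklevel=2)
    return Structure(atoms=atoms, title=title)
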