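"""Structure ingestion for docked nanobody–antigen complexes.

A complex arrives as PDB text (the pose an FFT docking engine emits). The
only information the downstream contact analysis needs is, per atom: chain,
residue identity in author numbering (with insertion code), atom name,
element and Cartesian coordinates. gemmi does the heavy lifting of the
fixed-column format; this module filters the parse down to the convention
the pipeline uses everywhere:

* waters (HOH) are dropped;
* for alternate locations, the first occurrence of each atom name within a
  residue is kept;
* non-standard residues such as the C-terminal NMA cap are retained as
  ordinary residues — they can be genuine contact partners;
* author residue numbers and insertion codes are preserved exactly, never
  renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import gemmi

__all__ = ["AtomRecord", "ResidueId", "Structure", "PdbParseError", "parse_structure"]


class PdbParseError(ValueError):
    """Raised when PDB text cannot be interpreted as coordinates."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbered residue key: (chain, name, number, insertion code)."""

    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "B/NMA 187A"
        return f"{self.chain_id}/{self.residue_name} {self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_name, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """A flat, ordered list of atoms from one model of a complex."""

    atoms: list[AtomRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select_chains(self, chain_ids: set[str]) -> "Structure":
        return Structure([a for a in self.atoms if a.chain_id in chain_ids])

    def residues(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)


_COORD_RECORDS = ("ATOM  ", "HETATM", "ATOM ")


def _prescan(pdb_text: str) -> int:
    """Validate the fixed-width coordinate fields; return the record count.

    gemmi is deliberately permissive, so malformed numeric columns are caught
    here with the offending line number.
    """
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        try:
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(f"line {lineno}: malformed fixed-width field ({exc})") from None
    return n


def _infer_element(atom_name: str, element: str) -> str:
    if element and element not in ("X", ""):
        return element
    # PDB convention: columns 13-14 hold the element, right-justified; strip
    # digits and greek-position letters from the short name.
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


_TWO_LETTER_ELEMENTS = {
    "Cl", "Br", "Fe", "Zn", "Mg", "Mn", "Na", "Ca", "Cu", "Ni", "Se", "Co",
}


def parse_structure(pdb_text: str, *, model_index: int = 0) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Keeps every ATOM and HETATM record except waters; for alternate
    locations the first occurrence per (residue, atom name) wins. Raises
    :class:`PdbParseError` when no coordinate records are present or a
    record's fixed-width fields are malformed (the message names the line).
    """
    if _prescan(pdb_text) == 0:
        raise PdbParseError("no ATOM or HETATM records found")
    st = gemmi.read_pdb_string(pdb_text)
    if model_index >= len(st):
        raise PdbParseError(f"model {model_index} not present ({len(st)} model(s))")
    atoms: list[AtomRecord] = []
    for chain in st[model_index]:
        for res in chain:
            if res.name == "HOH":
                continue
            seen_names: set[str] = set()
            for atom in res:
                if atom.name in seen_names:  # later altloc of an atom already kept
                    continue
                seen_names.add(atom.name)
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        atom_name=atom.name,
                        element=_infer_element(atom.name, atom.element.name),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise PdbParseError("no usable coordinate records after filtering")
    return Structure(atoms)
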