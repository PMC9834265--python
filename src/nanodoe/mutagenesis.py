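"""Point mutagenesis of nanobody sequences and CDR annotation.

Substitution-only: the protocol mutates side chains at fixed positions and
never inserts or deletes, so every variant has the base sequence's length.
Positions are plain sequential author numbering (1-based by default, with a
configurable offset); no Kabat/IMGT renumbering is performed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters, protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AminoAcidSequence",
    "PointMutation",
    "CdrMap",
    "MutationError",
    "apply_mutations",
    "variants_from_design",
    "cdr_membership",
    "mutate_to_assignment",
    "parse_mutations",
    "read_fasta",
    "write_fasta",
    "DEFAULT_CDR_MAP",
]

_VALID = set(protein_letters)  # the 20 one-letter codes
_3TO1 = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
MAX_LENGTH = 1000


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class AminoAcidSequence:
    """A named protein sequence with an author-numbering offset.

    ``offset`` maps author numbering to string index: author position p is
    ``residues[p - offset]`` with the default offset 1 (position 1 = first
    residue).
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        if len(self.residues) >= MAX_LENGTH:
            raise ValueError(f"sequence length {len(self.residues)} exceeds {MAX_LENGTH - 1}")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"invalid amino-acid codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def at(self, position: int) -> str:
        """Residue at an author-numbered position."""
        idx = position - self.offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(f"position {position} outside sequence {self.id!r}")
        return self.residues[idx]


@dataclass(frozen=True)
class PointMutation:
    """A single substitution in wt-position-mut notation, e.g. S27F."""

    wt: str
    position: int
    mut: str

    def __post_init__(self) -> None:
        for aa, what in ((self.wt, "wild-type"), (self.mut, "mutant")):
            if aa not in _VALID:
                raise ValueError(f"invalid {what} residue {aa!r}")
        if self.wt == self.mut:
            raise ValueError(f"mutation {self} is a no-op (wt == mut)")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def reverse(self) -> "PointMutation":
        return PointMutation(self.mut, self.position, self.wt)


_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutations(spec: str) -> list[PointMutation]:
    """Parse a comma-separated mutation string such as ``"S27F,T28W"``."""
    out = []
    for token in filter(None, (t.strip() for t in spec.split(","))):
        m = _MUT_RE.match(token)
        if not m:
            raise MutationError(f"cannot parse mutation token {token!r}")
        out.append(PointMutation(m.group(1), int(m.group(2)), m.group(3)))
    return out


def apply_mutations(seq: AminoAcidSequence, mutations: Sequence[PointMutation]) -> AminoAcidSequence:
    """Apply point mutations, validating the wild-type residue at each site.

    Returns a new sequence whose id is suffixed with the mutation list;
    duplicate positions or a wild-type mismatch raise :class:`MutationError`.
    """
    positions = [m.position for m in mutations]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise MutationError(f"duplicate mutated positions: {dupes}")
    chars = list(seq.residues)
    for m in mutations:
        idx = m.position - seq.offset
        if not 0 <= idx < len(chars):
            raise MutationError(f"position {m.position} outside sequence {seq.id!r} (length {len(chars)})")
        if chars[idx] != m.wt:
            raise MutationError(
                f"wild-type mismatch at position {m.position}: expected {m.wt}, found {chars[idx]}"
            )
        chars[idx] = m.mut
    suffix = "+".join(str(m) for m in mutations)
    new_id = f"{seq.id}|{suffix}" if suffix else seq.id
    return AminoAcidSequence(id=new_id, residues="".join(chars), offset=seq.offset)


def mutate_to_assignment(
    seq: AminoAcidSequence,
    assignment: Mapping[int, str],
    *,
    name: str | None = None,
) -> AminoAcidSequence:
    """Mutate ``seq`` so each position carries the assigned amino acid.

    Levels may be 3-letter codes (as in design tables) or 1-letter codes.
    Positions already at the target residue are left untouched.
    """
    mutations = []
    for pos in sorted(assignment):
        aa = assignment[pos]
        one = _3TO1.get(aa.capitalize(), aa) if len(aa) == 3 else aa
        if one not in _VALID:
            raise MutationError(f"unknown amino acid {aa!r} at position {pos}")
        try:
            wt = seq.at(pos)
        except IndexError as exc:
            raise MutationError(str(exc)) from None
        if wt != one:
            mutations.append(PointMutation(wt, pos, one))
    mutated = apply_mutations(seq, mutations)
    if name is not None:
        mutated = AminoAcidSequence(id=name, residues=mutated.residues, offset=mutated.offset)
    return mutated


def variants_from_design(
    seq: AminoAcidSequence,
    design,
    *,
    wt_map: Mapping[int, str] | None = None,
) -> list[AminoAcidSequence]:
    """One mutated sequence per design run, named run-01, run-02, ...

    ``wt_map`` (position -> expected wild-type, 1- or 3-letter) is checked
    against the base sequence before any variant is built.
    """
    if wt_map:
        for pos, aa in wt_map.items():
            one = _3TO1.get(aa.capitalize(), aa) if len(aa) == 3 else aa
            found = seq.at(pos)
            if found != one:
                raise MutationError(
                    f"wild-type map mismatch at position {pos}: expected {one}, found {found}"
                )
    width = max(2, len(str(design.n_runs)))
    return [
        mutate_to_assignment(seq, row, name=f"{seq.id}|run-{r:0{width}d}")
        for r, row in enumerate(design.rows, start=1)
    ]


@dataclass(frozen=True)
class CdrMap:
    """Inclusive residue intervals of the three CDR loops."""

    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]

    def __post_init__(self) -> None:
        ranges = [self.cdr1, self.cdr2, self.cdr3]
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"empty CDR interval ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(ranges, ranges[1:]):
            if lo <= hi:
                raise ValueError("CDR intervals must be ascending and non-overlapping")


#: Sequential CDR ranges of the anti-CD20 nanobody study.
DEFAULT_CDR_MAP = CdrMap(cdr1=(26, 33), cdr2=(51, 57), cdr3=(96, 108))


def cdr_membership(position: int, cdr_map: CdrMap = DEFAULT_CDR_MAP) -> str:
    """Classify a position as CDR1, CDR2, CDR3 or framework."""
    if position < 1:
        raise ValueError("positions are 1-based")
    for name, (lo, hi) in (("CDR1", cdr_map.cdr1), ("CDR2", cdr_map.cdr2), ("CDR3", cdr_map.cdr3)):
        if lo <= position <= hi:
            return name
    return "framework"


def read_fasta(text_or_path, *, offset: int = 1) -> list[AminoAcidSequence]:
    """Read protein FASTA from a path or raw text."""
    if isinstance(text_or_path, str) and text_or_path.lstrip().startswith(">"):
        handle = io.StringIO(text_or_path)
    else:
        handle = open(text_or_path)
    with handle:
        return [
            AminoAcidSequence(id=rec.id, residues=str(rec.seq).upper(), offset=offset)
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(sequences: Iterable[AminoAcidSequence], path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
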