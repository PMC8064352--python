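"""Sequences, secondary structures, file formats and the F1 accuracy measure.

RNA secondary structures are modelled as sets of 1-based base pairs (i, j),
i < j, that are pseudoknot-free (non-crossing), with each position in at most
one pair and at least three unpaired nucleotides enclosed by every hairpin
(j - i >= 4).  When bound to a sequence, pairs must be canonical: Watson-Crick
(AU, UA, CG, GC) or wobble (GU, UG).

Supported formats: FASTA for sequences; dot-bracket, CT (6-column) and BPSEQ
(3-column) for structures.  Coordinates are 1-based in every format and in the
internal model.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureError",
    "read_fasta",
    "write_fasta",
    "read_structure",
    "write_structure",
    "clean_reference",
    "f1_accuracy",
    "CANONICAL_PAIRS",
]

#: Base pairs accepted when a structure is bound to a sequence.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

_ALPHABET = frozenset("ACGU")

#: Minimum number of unpaired nucleotides enclosed by a hairpin loop.
MIN_HAIRPIN_UNPAIRED = 3


class StructureError(ValueError):
    """Raised for malformed or invalid sequences and structures."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}.

    DNA input is accepted transparently: lowercase letters are uppercased and
    T is mapped to U before validation.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        mapped = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", mapped)
        if not mapped:
            raise StructureError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(mapped, start=1):
            if ch not in _ALPHABET:
                raise StructureError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def gc_content(self) -> Fraction:
        n_gc = sum(1 for ch in self.residues if ch in "GC")
        return Fraction(n_gc, len(self.residues))


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure on ``length`` nucleotides.

    ``pairs`` is a frozenset of 1-based (i, j) tuples with i < j.  Validity
    (occupancy, non-crossing, hairpin size) is enforced at construction.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        if self.length <= 0:
            raise StructureError("structure length must be positive")
        seen: dict[int, tuple] = {}
        for i, j in sorted(self.pairs):
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair {(i, j)} out of range for length {self.length}")
            if j - i < MIN_HAIRPIN_UNPAIRED + 1:
                raise StructureError(
                    f"hairpin constraint violated: pair {(i, j)} encloses "
                    f"{j - i - 1} nt (< {MIN_HAIRPIN_UNPAIRED})"
                )
            for k in (i, j):
                if k in seen:
                    raise StructureError(f"position {k} occurs in pairs {seen[k]} and {(i, j)}")
                seen[k] = (i, j)
        crossings = _find_crossings(self.pairs)
        if crossings:
            raise StructureError(f"crossing pairs (pseudoknot): {crossings[:3]}")

    def __len__(self) -> int:
        return self.length

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def _find_crossings(pairs: Iterable[tuple]) -> list[tuple]:
    ps = sorted(pairs)
    bad = []
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if k > j:
                break
            if i < k < j < l:
                bad.append(((i, j), (k, l)))
    return bad


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[RnaSequence]:
    """Read and validate all sequences from a FASTA file (T mapped to U)."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise StructureError(
                    f"{path.name}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            break
        else:
            raise StructureError(f"{path.name}: no FASTA records found")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureError(f"{path.name}: no FASTA records found")
    return [RnaSequence(id=rec.id, residues=str(rec.seq)) for rec in records]


def write_fasta(path, sequences: Sequence[RnaSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


# ---------------------------------------------------------------------------
# Structure formats
# ---------------------------------------------------------------------------

def read_structure(path, format: str) -> SecondaryStructure:
    """Read a structure from ``path`` in one of dotbracket | ct | bpseq."""
    text = Path(path).read_text()
    return parse_structure(text, format)


def parse_structure(text: str, format: str) -> SecondaryStructure:
    if format == "dotbracket":
        return _parse_dotbracket(text)
    if format == "ct":
        return _parse_ct(text)
    if format == "bpseq":
        return _parse_bpseq(text)
    raise ValueError(f"unknown structure format {format!r}")


def _parse_dotbracket(text: str) -> SecondaryStructure:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith(">")]
    if not lines:
        raise StructureError("empty dot-bracket input")
    db = lines[-1] if len(lines) > 1 else lines[0]
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal dot-bracket character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(length=len(db), pairs=frozenset(pairs))


def _pairs_from_columns(rows: list[tuple]) -> frozenset:
    """Validate symmetric 1-based pair columns (0 = unpaired) -> pair set."""
    partner = {i: p for i, p in rows}
    pairs = set()
    for i, p in rows:
        if p == 0:
            continue
        if partner.get(p) != i:
            raise StructureError(f"pair asymmetry: {i} pairs {p} but {p} pairs {partner.get(p)}")
        if p == i:
            raise StructureError(f"position {i} pairs itself")
        if i < p:
            pairs.add((i, p))
    return frozenset(pairs)


def _parse_ct(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT input")
    header = lines[0].split()
    try:
        length = int(header[0])
    except (IndexError, ValueError):
        raise StructureError(f"malformed CT header: {lines[0]!r}") from None
    rows = []
    for ln in lines[1 : length + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise StructureError(f"malformed CT row: {ln!r}")
        rows.append((int(cols[0]), int(cols[4])))
    if len(rows) != length:
        raise StructureError(f"CT: expected {length} rows, found {len(rows)}")
    return SecondaryStructure(length=length, pairs=_pairs_from_columns(rows))


def _parse_bpseq(text: str) -> SecondaryStructure:
    rows = []
    for ln in text.splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 3:
            raise StructureError(f"malformed BPSEQ row: {ln!r}")
        rows.append((int(cols[0]), int(cols[2])))
    if not rows:
        raise StructureError("empty BPSEQ input")
    return SecondaryStructure(length=max(i for i, _ in rows), pairs=_pairs_from_columns(rows))


def write_structure(path, structure: SecondaryStructure, format: str,
                    sequence: RnaSequence | None = None) -> None:
    Path(path).write_text(format_structure(structure, format, sequence))


def format_structure(structure: SecondaryStructure, format: str,
                     sequence: RnaSequence | None = None) -> str:
    res = sequence.residues if sequence is not None else "N" * structure.length
    name = sequence.id if sequence is not None else "structure"
    partner = structure.partner_map()
    if format == "dotbracket":
        return structure.to_dotbracket() + "\n"
    if format == "ct":
        buf = _io.StringIO()
        buf.write(f"{structure.length} {name}\n")
        for i in range(1, structure.length + 1):
            nxt = i + 1 if i < structure.length else 0
            buf.write(f"{i} {res[i - 1]} {i - 1} {nxt} {partner.get(i, 0)} {i}\n")
        return buf.getvalue()
    if format == "bpseq":
        return "".join(
            f"{i} {res[i - 1]} {partner.get(i, 0)}\n" for i in range(1, structure.length + 1)
        )
    raise ValueError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# Reference cleaning and accuracy
# ---------------------------------------------------------------------------

def is_canonical(sequence: RnaSequence, pair: tuple) -> bool:
    i, j = pair
    return (sequence.residues[i - 1], sequence.residues[j - 1]) in CANONICAL_PAIRS


def clean_reference(structure: SecondaryStructure,
                    sequence: RnaSequence) -> SecondaryStructure:
    """Drop noncanonical pairs from a reference structure.

    Crossing pairs are never silently resolved: the structure model rejects
    them outright, so a pseudoknotted reference must be curated upstream.
    """
    if structure.length != len(sequence):
        raise StructureError(
            f"structure length {structure.length} != sequence length {len(sequence)}"
        )
    kept = frozenset(p for p in structure.pairs if is_canonical(sequence, p))
    return SecondaryStructure(length=structure.length, pairs=kept)


def validate_bound(sequence: RnaSequence, structure: SecondaryStructure) -> None:
    """Check that every pair of ``structure`` is canonical on ``sequence``."""
    if structure.length != len(sequence):
        raise StructureError(
            f"structure length {structure.length} != sequence length {len(sequence)}"
        )
    for i, j in sorted(structure.pairs):
        if not is_canonical(sequence, (i, j)):
            raise StructureError(
                f"noncanonical pair {(i, j)}: "
                f"{sequence.residues[i - 1]}-{sequence.residues[j - 1]}"
            )


def f1_accuracy(s1: SecondaryStructure, s2: SecondaryStructure) -> Fraction:
    """F1 measure 2|S1 ∩ S2| / (|S1| + |S2|) between two pair sets.

    Two empty structures agree perfectly (1); exactly one empty scores 0.
    Exact rational output.
    """
    if s1.length != s2.length:
        raise StructureError(f"length mismatch: {s1.length} != {s2.length}")
    n1, n2 = len(s1.pairs), len(s2.pairs)
    if n1 == 0 and n2 == 0:
        return Fraction(1)
    if n1 == 0 or n2 == 0:
        return Fraction(0)
    return Fraction(2 * len(s1.pairs & s2.pairs), n1 + n2)
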