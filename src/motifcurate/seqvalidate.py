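"""Consensus-pattern parsing and protein-sequence validation.

A minimotif consensus such as ``[RK]xx[RK]`` is a sequence of elements:
literal residues (one of the 20 amino-acid letters), residue classes
(``[RK]`` — any of the bracketed letters), and the lower-case wildcard
``x`` which matches any residue.  Upper-case ``X`` in a protein sequence is
an *unknown residue* and is matched only by the wildcard, never by a
literal or a class.

The validator checks an annotation's claimed 1-based start position against
all occurrences of its motif in the source protein, returning the matched
span for highlighting when the claim holds.  Positions are 1-based with
inclusive ends throughout the public interface; 0-based half-open spans are
an internal convenience with a tested bijection between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO

from Bio import SeqIO

from .annotation import MinimotifRecord

__all__ = [
    "AMINO_ACIDS",
    "ConsensusParseError",
    "FastaError",
    "ValidationError",
    "ConsensusPattern",
    "ProteinSequence",
    "parse_consensus",
    "find_occurrences",
    "validate_position",
    "read_fasta",
    "to_half_open",
    "to_one_based",
]

#: The 20 standard amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Sentinel element representing the wildcard position.
WILDCARD = None


class ConsensusParseError(ValueError):
    """Malformed consensus text; carries the character offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class FastaError(ValueError):
    """Malformed FASTA input."""


class ValidationError(ValueError):
    """Wrong sequence supplied or unusable record."""


@dataclass(frozen=True)
class ConsensusPattern:
    """Parsed consensus: a tuple of elements, each a frozenset of allowed
    residues or ``None`` for the wildcard."""

    elements: tuple[frozenset[str] | None, ...]
    text: str = ""

    def __post_init__(self) -> None:
        if len(self.elements) < 1:
            raise ConsensusParseError("empty consensus", 0)
        for el in self.elements:
            if el is WILDCARD:
                continue
            if not el or not el <= AMINO_ACIDS:
                raise ConsensusParseError("invalid residue class", 0)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence; residues upper-case, ``X`` = unknown residue."""

    accession: str
    residues: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaError("sequence requires a non-empty accession")
        if not self.residues:
            raise FastaError(f"{self.accession}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise FastaError(
                f"{self.accession}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def parse_consensus(text: str) -> ConsensusPattern:
    """Parse consensus notation left to right.

    ``x`` is the wildcard; ``[..]`` encloses a residue class; any of the 20
    upper-case amino-acid letters stands for itself.  Errors report the
    character offset.
    """
    elements: list[frozenset[str] | None] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "x":
            elements.append(WILDCARD)
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise ConsensusParseError("unbalanced '['", i)
            letters = text[i + 1 : j]
            if not letters:
                raise ConsensusParseError("empty residue class", i)
            bad = set(letters) - AMINO_ACIDS
            if bad:
                raise ConsensusParseError(
                    f"invalid residue letter {sorted(bad)[0]!r} in class", i
                )
            elements.append(frozenset(letters))
            i = j + 1
        elif ch == "]":
            raise ConsensusParseError("unbalanced ']'", i)
        elif ch in AMINO_ACIDS:
            elements.append(frozenset(ch))
            i += 1
        else:
            raise ConsensusParseError(f"invalid character {ch!r}", i)
    if not elements:
        raise ConsensusParseError("empty consensus", 0)
    return ConsensusPattern(tuple(elements), text)


def _to_regex(pattern: ConsensusPattern) -> str:
    parts = []
    for el in pattern.elements:
        if el is WILDCARD:
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(el)) + "]")
    return "".join(parts)


def find_occurrences(
    pattern: ConsensusPattern, seq: ProteinSequence
) -> list[int]:
    """All 1-based start positions where the pattern matches, ascending.

    Overlapping occurrences are all reported.  A pattern longer than the
    sequence yields an empty list.
    """
    if len(pattern) > len(seq):
        return []
    # lookahead regex reports overlapping matches
    rx = re.compile("(?=" + _to_regex(pattern) + ")")
    return [m.start() + 1 for m in rx.finditer(seq.residues)]


def validate_position(
    record: MinimotifRecord, seq: ProteinSequence
) -> tuple[bool, tuple[int, int] | None]:
    """Check a record's claimed motif position against the sequence.

    Returns ``(True, (start, end))`` — 1-based inclusive span for
    highlighting — when the motif occurs at the claimed position, else
    ``(False, None)``.  A consensus with several occurrences validates at
    any of them.
    """
    if seq.accession != record.source_accession:
        raise ValidationError(
            f"sequence {seq.accession!r} does not match record accession "
            f"{record.source_accession!r}"
        )
    if record.position is None:
        raise ValidationError("record has no claimed position to validate")
    pattern = parse_consensus(record.motif)
    if record.position in find_occurrences(pattern, seq):
        return True, (record.position, record.position + len(pattern) - 1)
    return False, None


def read_fasta(text: str) -> list[ProteinSequence]:
    """Read FASTA text; the accession is the first header token.

    Sequences are upper-cased with line breaks removed.  Empty input and
    sequence text before the first header are parse errors.
    """
    stripped = text.lstrip()
    if not stripped:
        raise FastaError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FastaError("FASTA records must start with a '>' header line")
    seqs: list[ProteinSequence] = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seqs.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    return seqs


def to_half_open(position: int, length: int) -> tuple[int, int]:
    """1-based inclusive (position, length) -> 0-based half-open (start, end)."""
    if position < 1 or length < 1:
        raise ValueError("position and length must be >= 1")
    return position - 1, position - 1 + length


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (start, end) -> 1-based (position, length)."""
    if start < 0 or end <= start:
        raise ValueError("need 0 <= start < end")
    return start + 1, end - start
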