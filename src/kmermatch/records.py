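"""Core record types: proteins, query sets, and reported matches.

Coordinates are 0-based throughout the library; the result writer in
:mod:`kmermatch.io_formats` converts to 1-based inclusive coordinates at the
file boundary. Mismatch positions inside a peptide are 1-based, matching how
substitution positions are reported in epitope work (position 1 = first
residue of the peptide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError

#: The 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical residues plus the ambiguity/rare codes permitted literally.
#: X (any), B (Asx), Z (Glx), U (selenocysteine), O (pyrrolysine) are indexed
#: and compared as plain characters: X matches only X.
EXTENDED_AA = CANONICAL_AA + "XBZUO"

_ALLOWED = frozenset(EXTENDED_AA)


def validate_sequence(seq: str, *, what: str = "sequence") -> None:
    """Raise :class:`InvalidInputError` unless *seq* is a nonempty uppercase
    amino-acid string over the permitted alphabet."""
    if not seq:
        raise InvalidInputError(f"{what} is empty")
    bad = set(seq) - _ALLOWED
    if bad:
        raise InvalidInputError(
            f"{what} contains illegal residue character(s): {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry with parsed UniProt-style metadata.

    Optional metadata fields default to empty strings / ``None`` when the
    header carries no such information (non-UniProt headers).
    """

    accession: str
    sequence: str
    name: str = ""
    gene: str = ""
    species: str = ""
    taxon_id: int | None = None
    existence_level: int | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise InvalidInputError("protein accession must be nonempty")
        validate_sequence(self.sequence, what=f"sequence of {self.accession}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QuerySet:
    """Ordered peptides to search, as (query_id, sequence) pairs.

    Duplicate sequences are permitted; each input row is reported
    independently. Sequences must be length >= 2 (a single residue carries no
    positional information worth matching).
    """

    peptides: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for qid, seq in self.peptides:
            validate_sequence(seq, what=f"query {qid}")
            if len(seq) < 2:
                raise InvalidInputError(f"query {qid} is shorter than 2 residues")

    @classmethod
    def from_sequences(cls, seqs: "list[str]") -> "QuerySet":
        """Wrap bare sequences, auto-assigning ids q1..qn."""
        return cls([(f"q{i + 1}", s) for i, s in enumerate(seqs)])

    def by_length(self) -> dict[int, list[tuple[str, str]]]:
        groups: dict[int, list[tuple[str, str]]] = {}
        for qid, seq in self.peptides:
            groups.setdefault(len(seq), []).append((qid, seq))
        return groups

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)


@dataclass(frozen=True)
class Match:
    """One reported hit of a query peptide inside a single protein.

    ``start``/``end`` are 0-based inclusive positions within the protein;
    ``mismatch_positions`` are 1-based positions within the peptide.
    """

    query_id: str
    query_sequence: str
    matched_sequence: str
    accession: str
    protein_name: str = ""
    gene: str = ""
    species: str = ""
    taxon_id: int | None = None
    existence_level: int | None = None
    start: int = 0
    end: int = 0
    mismatch_count: int = 0
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        """Check the Match's internal consistency (used by tests)."""
        assert len(self.query_sequence) == len(self.matched_sequence)
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.query_sequence, self.matched_sequence))
            if a != b
        ]
        assert self.mismatch_count == len(diffs) == len(self.mismatch_positions)
        assert list(self.mismatch_positions) == diffs
        assert self.end == self.start + len(self.query_sequence) - 1

    def key(self) -> tuple[str, str, str, int]:
        """The identity key used for recall comparison:
        (query, matched sequence, protein ID, position)."""
        return (self.query_sequence, self.matched_sequence, self.accession, self.start)
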