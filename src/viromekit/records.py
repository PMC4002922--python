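"""Core domain types shared across the toolkit.

All internal coordinates are 0-based half-open. The BLAST-tabular and
GenBank surfaces keep their native 1-based inclusive conventions; the
converters live in :mod:`viromekit.io` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import DataError

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, alphabet ``ACGTN``)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise DataError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise DataError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Hit:
    """One similarity search result row (12-column tabular dialect).

    Query coordinates are forward (``q_start <= q_end``); a subject
    interval with ``s_start > s_end`` encodes a minus-strand alignment,
    as emitted by the search tools themselves.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self):
        if self.evalue < 0:
            raise DataError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.alignment_length < 1:
            raise DataError(f"hit {self.query_id}->{self.subject_id}: alignment length < 1")
        if self.q_start > self.q_end:
            raise DataError(
                f"hit {self.query_id}->{self.subject_id}: query coordinates reversed"
            )
        if not 0 <= self.percent_identity <= 100:
            raise DataError(
                f"hit {self.query_id}->{self.subject_id}: identity outside [0,100]"
            )

    @property
    def subject_strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval (strand-normalized)."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain match from a per-target profile search table."""

    orf_id: str
    domain_accession: str
    domain_name: str
    score: float
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise DataError(f"domain hit for {self.orf_id}: negative e-value")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise DataError(f"domain hit for {self.orf_id}: non-finite score")


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomic path, root first, leaf (species) last."""

    ranks: tuple[str, ...]

    def __post_init__(self):
        if not self.ranks:
            raise DataError("empty lineage")
        if any(not r for r in self.ranks):
            raise DataError(f"lineage {self.ranks}: empty rank name")
        for a, b in zip(self.ranks, self.ranks[1:]):
            if a == b:
                raise DataError(f"lineage {self.ranks}: duplicate adjacent rank {a!r}")

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        return cls(tuple(r.strip() for r in text.split(sep)))

    def __str__(self) -> str:
        return ";".join(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ranks)

    def common_prefix(self, other: "Lineage") -> tuple[str, ...]:
        prefix = []
        for a, b in zip(self.ranks, other.ranks):
            if a != b:
                break
            prefix.append(a)
        return tuple(prefix)


@dataclass
class TaxonomyTable:
    """Reference taxonomy: lineage and genome length per reference id."""

    entries: dict[str, Lineage] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for ref, length in self.genome_lengths.items():
            if ref not in self.entries:
                raise DataError(f"genome length given for {ref} but no lineage")
            if length < 1:
                raise DataError(f"non-positive genome length for {ref}: {length}")

    def lineage(self, reference_id: str) -> Lineage:
        try:
            return self.entries[reference_id]
        except KeyError:
            raise DataError(f"unknown reference id: {reference_id}") from None

    def length(self, reference_id: str) -> int:
        try:
            return self.genome_lengths[reference_id]
        except KeyError:
            raise DataError(f"no genome length for reference: {reference_id}") from None

    def family(self, reference_id: str) -> str:
        """Family-level taxon (third rank of a root;order;family;species path)."""
        ranks = self.lineage(reference_id).ranks
        return ranks[min(2, len(ranks) - 1)]

    def __contains__(self, reference_id: str) -> bool:
        return reference_id in self.entries


def group_hits_by_query(hits) -> Mapping[str, list[Hit]]:
    """Group a hit table by query id, preserving first-seen query order."""
    grouped: dict[str, list[Hit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped
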