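"""Shared sequence data model: strain proteomes and annotation-transfer QC.

All coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

#: the three strain roles a proteome can play in the screen
STRAINS = ("susceptible", "resistant", "reference")

#: 20 canonical residues plus 'X' for unknown
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

_ALPHABET_SET = frozenset(ALPHABET)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_strain(strain: str) -> str:
    if strain not in STRAINS:
        raise ValueError(f"strain must be one of {STRAINS}, got {strain!r}")
    return strain


@dataclass
class ProteinRecord:
    """One protein sequence of one strain, keyed by transcript ID.

    ``has_start`` is always recomputed from the sequence (leading 'M');
    ``cds_complete`` records whether the annotation reported both start and
    stop codons, which truncation artifacts clear.
    """

    transcript_id: str
    gene_id: str
    strain: str
    sequence: str
    cds_complete: bool = True
    has_start: bool = field(init=False)

    def __post_init__(self) -> None:
        _check_strain(self.strain)
        if not self.transcript_id or any(c.isspace() for c in self.transcript_id):
            raise ValueError(
                f"transcript_id must be a whitespace-free token, got {self.transcript_id!r}"
            )
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid residue(s) {sorted(bad)!r} "
                f"(allowed: {ALPHABET})"
            )
        self.has_start = self.sequence.startswith("M")

    def with_sequence(
        self, sequence: str, cds_complete: Optional[bool] = None
    ) -> "ProteinRecord":
        """Copy of this record with a new sequence (flags recomputed)."""
        return ProteinRecord(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            strain=self.strain,
            sequence=sequence,
            cds_complete=self.cds_complete if cds_complete is None else cds_complete,
        )

    def with_strain(self, strain: str) -> "ProteinRecord":
        return ProteinRecord(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            strain=strain,
            sequence=self.sequence,
            cds_complete=self.cds_complete,
        )


@dataclass
class StrainProteome:
    """All protein records of one strain, keyed by transcript ID."""

    strain: str
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_strain(self.strain)
        for tid, rec in self.records.items():
            if rec.strain != self.strain:
                raise ValueError(
                    f"record {tid} has strain {rec.strain!r}, proteome is {self.strain!r}"
                )
            if rec.transcript_id != tid:
                raise ValueError(
                    f"record keyed {tid!r} has transcript_id {rec.transcript_id!r}"
                )

    def add(self, record: ProteinRecord) -> None:
        if record.transcript_id in self.records:
            raise FormatError(f"duplicate transcript_id {record.transcript_id!r}")
        if record.strain != self.strain:
            raise ValueError(
                f"record {record.transcript_id} has strain {record.strain!r}, "
                f"proteome is {self.strain!r}"
            )
        self.records[record.transcript_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.records

    def __getitem__(self, transcript_id: str) -> ProteinRecord:
        return self.records[transcript_id]

    def ids(self) -> list[str]:
        return sorted(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrainProteome):
            return NotImplemented
        return self.strain == other.strain and self.records == other.records


@dataclass(frozen=True)
class ContigContext:
    """Placement of one gene on its contig, for fragmentation checks."""

    contig_id: str
    contig_length: int
    gene_start: int
    gene_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.contig_length <= 0:
            raise ValueError("contig_length must be positive")
        if not (1 <= self.gene_start <= self.gene_end <= self.contig_length):
            raise ValueError(
                f"require 1 <= gene_start ({self.gene_start}) <= gene_end "
                f"({self.gene_end}) <= contig_length ({self.contig_length})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def distance_to_edge(self) -> int:
        """bp from the gene to the nearest contig boundary."""
        return min(self.gene_start - 1, self.contig_length - self.gene_end)


@dataclass(frozen=True)
class TransferAttributes:
    """Per-transcript QC attributes from the annotation-transfer GFF3."""

    transcript_id: str
    matches_ref_protein: bool = True
    missing_start: bool = False
    missing_stop: bool = False
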