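"""Core genomic data model.

All coordinates are 0-based half-open (``[start, end)``) on the forward
genomic axis; conversion from 1-based inclusive GTF coordinates happens at
the I/O boundary.  Transcript-orientation comparisons use *directed*
coordinates: ``d5``/``d3`` are the 5'- and 3'-most positions of an interval
along the transcript, signed so that plus-strand logic applies unchanged on
the minus strand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable


class CodingType(enum.Enum):
    """Coding composition of an internal exon relative to its transcript's CDS."""

    TYPE1_5UTR = "Type1"
    TYPE2_5UC = "Type2"
    TYPE3_CDS = "Type3"
    TYPE4_C3U = "Type4"
    TYPE5_3UTR = "Type5"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SpliceClass(enum.Enum):
    """Splicing behaviour of an internal exon among the isoforms covering it."""

    CONSTITUTIVE = "constitutive"
    ASE = "ASE"
    SSE = "SSE"
    OTHER_ALT = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CODING_TYPES = list(CodingType)
SPLICE_CLASSES = list(SpliceClass)

#: Priority used when containing isoforms disagree on the coding type:
#: initiation-site-containing first, then termination, then pure UTR, CDS last.
TYPE_CONFLICT_PRIORITY = (
    CodingType.TYPE2_5UC,
    CodingType.TYPE4_C3U,
    CodingType.TYPE1_5UTR,
    CodingType.TYPE5_3UTR,
    CodingType.TYPE3_CDS,
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def d5(self) -> int:
        """Directed 5' boundary (signed so d5 < d3 on both strands)."""
        return self.start if self.strand == "+" else -self.end

    @property
    def d3(self) -> int:
        """Directed 3' boundary."""
        return self.end if self.strand == "+" else -self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def coords(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    """One transcript isoform: exons and (optionally) CDS segments.

    ``exons`` and ``cds`` are stored in transcript orientation (5'->3'):
    ascending genomic coordinates on '+', descending on '-'.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.d5)
        self.cds = sorted(self.cds, key=lambda c: c.d5)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.d3 > b.d5:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping/unordered exons"
                )
        for seg in self.cds:
            if not any(e.contains(seg) for e in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS segment "
                    f"{seg.chrom}:{seg.start}-{seg.end} not contained in any exon"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def span(self) -> GenomicInterval:
        """Genomic extent from the first exon's start to the last exon's end."""
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def cds_span(self) -> tuple[int, int] | None:
        """(d5, d3) of the CDS in directed coordinates, or None if non-coding."""
        if not self.cds:
            return None
        return (min(c.d5 for c in self.cds), max(c.d3 for c in self.cds))

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    def exon_coords(self) -> set[tuple[str, int, int, str]]:
        return {e.coords() for e in self.exons}

    def junctions(self) -> list[tuple[int, int]]:
        """Genomic (donor_end, acceptor_start) pairs between adjacent exons.

        Returned in ascending genomic order regardless of strand, matching
        junction-count table keys.
        """
        ex = sorted(self.exons, key=lambda e: e.start)
        return [(a.end, b.start) for a, b in zip(ex, ex[1:])]


@dataclass
class GeneModel:
    """A protein-coding gene with one or more transcript isoforms."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    swissprot_validated: bool = False

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on a "
                    "different chromosome or strand"
                )


@dataclass
class InternalExonRecord:
    """A unique internal exon of a gene, with audit information."""

    interval: GenomicInterval
    gene_id: str
    containing_transcripts: list[str]
    mixed_terminal: bool


@dataclass
class ClassifiedExon:
    """A unique internal exon with its coding type and splice class."""

    interval: GenomicInterval
    gene_id: str
    coding_type: CodingType
    splice_class: SpliceClass
    containing_transcripts: list[str]
    covering_transcripts: list[str]
    type_conflict: bool = False
    mixed_terminal: bool = False

    @property
    def length(self) -> int:
        return self.interval.length


def iter_exon_coords(genes: Iterable[GeneModel]) -> set[tuple[str, int, int, str]]:
    """All distinct exon coordinates over a gene collection (helper for audits)."""
    out: set[tuple[str, int, int, str]] = set()
    for g in genes:
        for t in g.transcripts:
            out |= t.exon_coords()
    return out
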