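"""Coding-composition and splice-class classification of internal exons.

Every unique internal exon of a multi-isoform coding gene gets

* a coding type from its position relative to the CDS of the isoforms that
  contain it: entirely 5'UTR (Type 1), spanning the translation initiation
  site (Type 2, "5UC"), entirely CDS (Type 3), spanning the stop (Type 4),
  entirely 3'UTR (Type 5); and
* a splice class from the isoforms whose genomic span covers it:
  constitutive, cassette/skipped (ASE), splice-site-shifted (SSE), or other
  alternative usage (typically overlap with an alternative terminal exon).

The 5UC-ASE intersection — cassette exons whose skipping deletes the start
codon — is the set of interest downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation import internal_exon_records
from .models import (
    CODING_TYPES,
    SPLICE_CLASSES,
    TYPE_CONFLICT_PRIORITY,
    ClassifiedExon,
    CodingType,
    GeneModel,
    GenomicInterval,
    SpliceClass,
    TranscriptModel,
)


def coding_composition(
    exon: GenomicInterval, transcript: TranscriptModel
) -> CodingType | None:
    """Coding type of ``exon`` within ``transcript``; None for non-coding isoforms.

    An exon containing both the start and the stop codon is Type 2
    (initiation-site-containing takes precedence).
    """
    if exon.coords() not in transcript.exon_coords():
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} not in transcript "
            f"{transcript.transcript_id}"
        )
    span = transcript.cds_span
    if span is None:
        return None
    c5, c3 = span
    if exon.d3 <= c5:
        return CodingType.TYPE1_5UTR
    if exon.d5 < c5:  # CDS 5' end strictly inside (covers start+stop case too)
        return CodingType.TYPE2_5UC
    if exon.d3 <= c3:
        return CodingType.TYPE3_CDS
    if exon.d5 < c3:
        return CodingType.TYPE4_C3U
    return CodingType.TYPE5_3UTR


def assign_coding_type(
    exon: GenomicInterval, containing: list[TranscriptModel]
) -> tuple[CodingType | None, bool]:
    """Resolve one coding type per unique exon across its containing isoforms.

    Agreement gives that type; disagreement is resolved by the fixed priority
    Type2 > Type4 > Type1 > Type5 > Type3 with ``conflict=True``. Returns
    ``(None, False)`` when no containing isoform is coding (the exon is then
    excluded from the typed table).
    """
    if not containing:
        raise ValueError("no containing transcript")
    types = {
        t
        for t in (coding_composition(exon, tx) for tx in containing)
        if t is not None
    }
    if not types:
        return None, False
    if len(types) == 1:
        return next(iter(types)), False
    for t in TYPE_CONFLICT_PRIORITY:
        if t in types:
            return t, True
    raise AssertionError("unreachable")


def _covering_transcripts(
    exon: GenomicInterval, gene: GeneModel
) -> list[TranscriptModel]:
    return [t for t in gene.transcripts if t.span.contains(exon)]


def _boundary_variant(exon: GenomicInterval, tx: TranscriptModel) -> bool:
    """True if ``tx`` has an exon overlapping ``exon`` whose differing
    boundary is a genuine splice site (not the transcript's own terminus)."""
    n = len(tx.exons)
    for i, o in enumerate(tx.exons):
        if not o.overlaps(exon):
            continue
        if o.d5 != exon.d5 and i > 0:
            return True
        if o.d3 != exon.d3 and i < n - 1:
            return True
    return False


def assign_splice_class(exon: GenomicInterval, gene: GeneModel) -> SpliceClass:
    """Splice class of a unique internal exon within its gene.

    Rules, in order, over the covering isoforms (genomic span contains the
    exon): single-isoform gene or exact-coordinate presence in all covering
    isoforms -> constitutive; an overlapping exon with a shifted splice-site
    boundary -> SSE; complete absence from >= 1 covering isoform -> ASE;
    anything else (overlap only with boundary-shifted *terminal* exons) ->
    other alternative.
    """
    covering = _covering_transcripts(exon, gene)
    key = exon.coords()
    if len(gene.transcripts) == 1 or all(key in t.exon_coords() for t in covering):
        return SpliceClass.CONSTITUTIVE
    if any(_boundary_variant(exon, t) for t in covering):
        return SpliceClass.SSE
    if any(not any(o.overlaps(exon) for o in t.exons) for t in covering):
        return SpliceClass.ASE
    return SpliceClass.OTHER_ALT


@dataclass
class ClassificationSummary:
    """Coding-type x splice-class count table over all classified exons."""

    counts: pd.DataFrame  # index: Type1..Type5; columns: ASE, SSE, other, constitutive
    n_dropped_noncoding: int = 0
    n_conflicts: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_totals(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "Total", df.sum(axis=1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.with_totals().to_csv(path, sep="\t", index_label="ExonClass")


def classify_gene(gene: GeneModel) -> tuple[list[ClassifiedExon], int]:
    """Classify every unique internal exon of one gene.

    Returns the classified exons and the number of exons dropped because
    only non-coding isoforms contain them.
    """
    out: list[ClassifiedExon] = []
    dropped = 0
    for rec in internal_exon_records(gene):
        containing = [
            t
            for t in gene.transcripts
            if t.transcript_id in rec.containing_transcripts
        ]
        ctype, conflict = assign_coding_type(rec.interval, containing)
        if ctype is None:
            dropped += 1
            continue
        sclass = assign_splice_class(rec.interval, gene)
        covering = _covering_transcripts(rec.interval, gene)
        out.append(
            ClassifiedExon(
                interval=rec.interval,
                gene_id=gene.gene_id,
                coding_type=ctype,
                splice_class=sclass,
                containing_transcripts=rec.containing_transcripts,
                covering_transcripts=sorted(t.transcript_id for t in covering),
                type_conflict=conflict,
                mixed_terminal=rec.mixed_terminal,
            )
        )
    return out, dropped


def classify_all(
    genes: Iterable[GeneModel],
) -> tuple[list[ClassifiedExon], ClassificationSummary]:
    """Classify unique internal exons across a gene collection.

    The summary partitions every classified exon into exactly one
    (coding type, splice class) cell; exons contained only in non-coding
    isoforms are dropped and counted in the summary audit fields.
    """
    exons: list[ClassifiedExon] = []
    dropped = 0
    for gene in genes:
        ge, gd = classify_gene(gene)
        exons.extend(ge)
        dropped += gd
    counts = pd.DataFrame(
        0,
        index=[t.value for t in CODING_TYPES],
        columns=[c.value for c in SPLICE_CLASSES],
        dtype=int,
    )
    for e in exons:
        counts.loc[e.coding_type.value, e.splice_class.value] += 1
    summary = ClassificationSummary(
        counts=counts,
        n_dropped_noncoding=dropped,
        n_conflicts=sum(e.type_conflict for e in exons),
    )
    return exons, summary


def classified_to_frame(exons: list[ClassifiedExon]) -> pd.DataFrame:
    """BED6-compatible table of classified exons (plus audit columns)."""
    rows = []
    for e in exons:
        rows.append(
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "name": f"{e.gene_id}|{e.coding_type.value}|{e.splice_class.value}",
                "score": 0,
                "strand": e.interval.strand,
                "gene_id": e.gene_id,
                "coding_type": e.coding_type.value,
                "splice_class": e.splice_class.value,
                "type_conflict": e.type_conflict,
                "mixed_terminal": e.mixed_terminal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "gene_id",
            "coding_type",
            "splice_class",
            "type_conflict",
            "mixed_terminal",
        ],
    )
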