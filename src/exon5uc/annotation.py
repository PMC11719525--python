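"""GTF annotation I/O and internal-exon extraction.

Reads GENCODE/Ensembl-dialect GTF into :class:`~exon5uc.models.GeneModel`
objects restricted to protein-coding genes, converts coordinates to 0-based
half-open, and identifies the unique internal exons that are the substrate
of the coding-composition classification.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd

from .models import GeneModel, GenomicInterval, InternalExonRecord, TranscriptModel


class GtfParseError(ValueError):
    pass


class AnnotationValidationError(ValueError):
    pass


def _attr(feature: gffutils.Feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def strip_version(identifier: str) -> str:
    """Strip a trailing '.N' version suffix from a GENCODE/Ensembl identifier."""
    head, sep, tail = identifier.rpartition(".")
    if sep and tail.isdigit():
        return head
    return identifier


def read_gtf(path: str | Path, dialect: str = "gencode") -> list[GeneModel]:
    """Parse a GTF file into protein-coding :class:`GeneModel` objects.

    Parameters
    ----------
    path
        GTF file (uncompressed).
    dialect
        "gencode" (attribute ``gene_type``) or "ensembl" (``gene_biotype``);
        both attribute names are accepted regardless, the flag only documents
        the expected input.

    Notes
    -----
    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    When any transcript carries a ``tag "basic"`` attribute, only
    basic-tagged transcripts are retained, matching basic-annotation inputs;
    GTFs without the tag keep every transcript.
    """
    if dialect not in ("gencode", "ensembl"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    gene_meta: dict[str, dict] = {}
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    any_basic_tag = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"line {lineno}: malformed GTF row: {exc}") from exc
            if feat.end < feat.start:
                raise GtfParseError(
                    f"line {lineno}: end < start ({feat.start}-{feat.end})"
                )
            ftype = feat.featuretype
            if ftype not in ("gene", "transcript", "exon", "CDS"):
                continue
            gene_id = _attr(feat, "gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            biotype = _attr(feat, "gene_type", "gene_biotype")
            if ftype == "gene":
                gene_meta[gene_id] = {
                    "gene_name": _attr(feat, "gene_name") or gene_id,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": biotype,
                }
                continue
            tx_id = _attr(feat, "transcript_id")
            if tx_id is None:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            if tx_id not in tx_meta:
                tags = feat.attributes.get("tag", [])
                tx_meta[tx_id] = {
                    "gene_id": gene_id,
                    "basic": "basic" in tags,
                    "biotype": biotype,
                    "gene_name": _attr(feat, "gene_name"),
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                }
            elif "tag" in feat.attributes and "basic" in feat.attributes["tag"]:
                tx_meta[tx_id]["basic"] = True
            if tx_meta[tx_id]["basic"]:
                any_basic_tag = True
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            if ftype == "exon":
                exons.setdefault(tx_id, []).append(iv)
            elif ftype == "CDS":
                cds.setdefault(tx_id, []).append(iv)

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, meta in tx_meta.items():
        if tx_id not in exons:
            continue
        if any_basic_tag and not meta["basic"]:
            continue
        try:
            tx = TranscriptModel(
                transcript_id=tx_id,
                gene_id=meta["gene_id"],
                exons=exons[tx_id],
                cds=cds.get(tx_id, []),
            )
        except ValueError as exc:
            raise AnnotationValidationError(str(exc)) from exc
        genes.setdefault(meta["gene_id"], []).append(tx)

    out: list[GeneModel] = []
    for gene_id in sorted(genes):
        meta = gene_meta.get(gene_id)
        if meta is None:
            first = genes[gene_id][0]
            tmeta = tx_meta[first.transcript_id]
            meta = {
                "gene_name": tmeta["gene_name"] or gene_id,
                "chrom": tmeta["chrom"],
                "strand": tmeta["strand"],
                "biotype": tmeta["biotype"],
            }
        if meta["biotype"] != "protein_coding":
            continue
        txs = sorted(genes[gene_id], key=lambda t: t.transcript_id)
        out.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=meta["gene_name"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                transcripts=txs,
            )
        )
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GENCODE-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            span_start = min(t.span.start for t in g.transcripts)
            span_end = max(t.span.end for t in g.transcripts)
            attrs = f'gene_id "{g.gene_id}"; gene_type "protein_coding"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\texon5uc\tgene\t{span_start + 1}\t{span_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "protein_coding"; gene_name "{g.gene_name}";'
                )
                sp = t.span
                fh.write(
                    f"{g.chrom}\texon5uc\ttranscript\t{sp.start + 1}\t{sp.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\texon5uc\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{g.chrom}\texon5uc\tCDS\t{c.start + 1}\t{c.end}\t.\t{g.strand}\t0\t{tattrs}\n"
                    )


def internal_exon_records(gene: GeneModel) -> list[InternalExonRecord]:
    """Unique internal exons of a gene, with containing isoforms and audit flags.

    An exon counts as internal when it is neither the first nor the last exon
    in at least one transcript with >= 3 exons; exons also occurring as a
    terminal exon in another isoform are flagged ``mixed_terminal``.
    """
    internal: dict[tuple, set[str]] = {}
    terminal: set[tuple] = set()
    ivs: dict[tuple, GenomicInterval] = {}
    for t in gene.transcripts:
        if len(t.exons) >= 2:
            terminal.add(t.exons[0].coords())
            terminal.add(t.exons[-1].coords())
        if len(t.exons) < 3:
            continue
        for e in t.exons[1:-1]:
            key = e.coords()
            ivs[key] = e
            internal.setdefault(key, set()).add(t.transcript_id)
    # exact-coordinate containment may extend beyond the isoforms where the
    # exon is internal (e.g. it is terminal elsewhere); record all of them
    records = []
    for key in sorted(internal):
        containing = {
            t.transcript_id
            for t in gene.transcripts
            if key in t.exon_coords()
        }
        records.append(
            InternalExonRecord(
                interval=ivs[key],
                gene_id=gene.gene_id,
                containing_transcripts=sorted(containing),
                mixed_terminal=key in terminal,
            )
        )
    return records


def unique_internal_exons(gene: GeneModel) -> list[GenomicInterval]:
    """Deduplicated internal exon intervals of a gene (empty if none possible)."""
    return [r.interval for r in internal_exon_records(gene)]


def filter_swissprot(
    genes: Iterable[GeneModel], metadata: str | Path | pd.DataFrame
) -> list[GeneModel]:
    """Retain genes with >= 1 transcript mapped to a Swiss-Prot accession.

    ``metadata`` is a two-column (transcript_id, accession) TSV or DataFrame;
    transcript IDs are compared after stripping '.N' version suffixes. The
    ``swissprot_validated`` flag is set on every input gene. An empty metadata
    table produces a warning and an empty result.
    """
    if isinstance(metadata, (str, Path)):
        metadata = pd.read_csv(
            metadata, sep="\t", header=None, comment="#", dtype=str
        )
    if metadata.empty:
        warnings.warn("empty Swiss-Prot metadata: no gene is flagged validated")
        mapped: set[str] = set()
    else:
        mapped = {strip_version(str(t)) for t in metadata.iloc[:, 0]}
    kept = []
    for g in genes:
        g.swissprot_validated = any(
            strip_version(t.transcript_id) in mapped for t in g.transcripts
        )
        if g.swissprot_validated:
            kept.append(g)
    return kept
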