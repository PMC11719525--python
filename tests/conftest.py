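"""Shared fixtures: compact gene builders and a session-scoped synthetic dataset."""

from __future__ import annotations

import pytest

from exon5uc.models import GeneModel, GenomicInterval, TranscriptModel
from exon5uc.simulate import SimulationConfig, simulate_annotation


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def make_transcript(tid, exons, cds=(), gid="G1", chrom="chr1", strand="+"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
    )


def make_gene(isoforms, gid="G1", chrom="chr1", strand="+"):
    """isoforms: list of (tid, exon_spans, cds_spans) tuples."""
    txs = [
        make_transcript(tid, exons, cds, gid=gid, chrom=chrom, strand=strand)
        for tid, exons, cds in isoforms
    ]
    return GeneModel(
        gene_id=gid, gene_name=gid, chrom=chrom, strand=strand, transcripts=txs
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Default synthetic dataset: 20 planted (type, class) cells, 210 genes."""
    return simulate_annotation(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_files(sim_dataset, tmp_path_factory):
    """The synthetic dataset written out in every on-disk input format."""
    import pandas as pd

    from exon5uc.simulate import (
        simulate_coverage,
        simulate_junction_counts,
        simulate_knockdown,
        write_tpm_tsv,
    )
    from exon5uc.splicing import write_junction_gct

    out = tmp_path_factory.mktemp("simdata")
    ds = sim_dataset
    ds.write_gtf(out / "annotation.gtf")
    ds.write_fasta(out / "genome.fa")
    samples, tmap = simulate_junction_counts(ds)
    write_junction_gct(samples, out / "junctions.gct")
    pd.DataFrame(
        {"sample_id": list(tmap), "tissue": list(tmap.values())}
    ).to_csv(out / "tissue_map.tsv", sep="\t", index=False)
    track, _ = simulate_coverage(ds)
    track.to_bedgraph(out / "coverage.bedgraph")
    ctrl, kd, _ = simulate_knockdown(ds)
    write_tpm_tsv(ctrl, out / "tpm_ctrl.tsv")
    write_tpm_tsv(kd, out / "tpm_kd.tsv")
    return out
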