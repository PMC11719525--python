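"""Synthetic data with planted ground truth for every pipeline stage.

The generator emits a multi-isoform gene annotation whose unique internal
exons have known coding types and splice classes, junction read counts drawn
around known PSI values, coverage tracks with planted upstream-intron
enrichment, two-condition isoform abundances with planted knockdown effects,
and species gene sets descending from a planted tree.  Each artifact draws
from its own RNG stream derived from the master seed by a fixed label, so
adding artifacts never perturbs existing ones.

Templates (all three-exon loci with a focal cassette exon):

* constitutive — a single isoform;
* ASE — a second isoform that splices the flanks directly together;
* SSE — a second isoform whose middle exon shares the 3' splice site but
  uses a shifted 5' splice site (splice-site clusters come in pairs, so SSE
  quotas must be even);
* other — a second isoform whose *first* exon overlaps the focal exon with
  an extended 5' end (alternative terminal-exon usage, not a splice-site
  shift).

Coding types place the CDS so that the focal exon is pure 5'UTR (Type 1),
contains the start codon (Type 2 / 5UC), sits inside the CDS (Type 3),
contains the stop (Type 4) or is pure 3'UTR (Type 5). Focal exon lengths
are drawn log-normally around a per-type median (larger for Type 2,
mirroring the observed size bias of initiation-site-containing exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .annotation import write_gtf
from .coverage import CoverageTrack
from .features import revcomp
from .models import (
    CodingType,
    GeneModel,
    GenomicInterval,
    SpliceClass,
    TranscriptModel,
)

# fixed RNG stream labels (one stream per artifact)
_STREAM_ANNOTATION = 1
_STREAM_JUNCTIONS = 2
_STREAM_COVERAGE = 3
_STREAM_KNOCKDOWN = 4
_STREAM_SPECIES = 5

#: planted species tree: a balanced clock-like (ultrametric) topology over
#: ten vertebrate labels — a synthetic benchmark tree, not the real
#: vertebrate phylogeny.  Balance matters: Ward's variance criterion
#: inflates distances to large clusters, so deeply nested caterpillar
#: topologies are not recoverable by design, whereas balanced clock trees
#: are recovered reliably.
DEFAULT_TREE = (
    "((((human:1,macaque:1):2,(mouse:1,rat:1):2):2,"
    "((cow:1,chicken:1):2,(frog:2,shark:2):1):2):1,(zebrafish:2,medaka:2):4);"
)

#: default focal-exon median lengths (nt); Type 2 exons run larger
DEFAULT_MEDIANS = {
    CodingType.TYPE1_5UTR: 122,
    CodingType.TYPE2_5UC: 161,
    CodingType.TYPE3_CDS: 122,
    CodingType.TYPE4_C3U: 122,
    CodingType.TYPE5_3UTR: 122,
}


def default_quotas(per_cell: int = 12) -> dict[tuple[CodingType, SpliceClass], int]:
    """Quota table covering all 20 (type, class) cells.

    SSE cells get an even count (splice-site clusters are planted in pairs).
    """
    quotas = {}
    for ct in CodingType:
        for sc in SpliceClass:
            n = per_cell
            if sc is SpliceClass.SSE:
                n = per_cell + (per_cell % 2)
            quotas[(ct, sc)] = n
    return quotas


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator (randomness flows from seed)."""

    seed: int = 0
    quotas: dict[tuple[CodingType, SpliceClass], int] = field(
        default_factory=default_quotas
    )
    medians: dict[CodingType, int] = field(
        default_factory=lambda: dict(DEFAULT_MEDIANS)
    )
    length_sigma: float = 0.35
    #: draw event PSIs uniformly from this range instead of the bimodal
    #: mixture (e.g. (0.2, 0.6) for a moderately included event panel)
    psi_uniform: tuple[float, float] | None = None
    # junction counts
    depth: float = 200.0
    tissues: dict[str, float] = field(
        default_factory=lambda: {
            "brain": -0.25,
            "muscle": -0.15,
            "testis": -0.15,
            "liver": 0.0,
            "heart": 0.0,
            "lung": 0.0,
            "spleen": 0.0,
            "kidney": 0.0,
            "pancreas": 0.0,
            "skin": 0.0,
        }
    )
    samples_per_tissue: int = 5
    # coverage
    bound_fraction: float = 0.5
    fold: float = 1.5
    width: int = 500
    lambda_bg: float = 8.0
    cov_bin: int = 10
    # knockdown
    kd_effect: float = 0.3
    kd_down_fraction: float = 0.2
    noise_sigma: float = 0.1
    total_tpm: float = 100.0
    # species evolution
    tree: str = DEFAULT_TREE
    loss_rate: float = 0.15
    pool_size: int = 300

    def __post_init__(self) -> None:
        for (ct, sc), n in self.quotas.items():
            if n < 0:
                raise ValueError("quotas must be >= 0")
            if sc is SpliceClass.SSE and n % 2:
                raise ValueError(
                    f"infeasible quota for {ct.value}-SSE: splice-site clusters "
                    "are planted in pairs, the count must be even"
                )
        if not -1.0 <= self.kd_effect <= 1.0:
            raise ValueError("kd_effect must be in [-1, 1]")
        if self.fold < 1.0:
            raise ValueError("enrichment fold must be >= 1")

    def stream(self, label: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(label)])


def _draw_psi(rng: np.random.Generator) -> float:
    """Bimodal PSI mixture: peaks near 0 and 1, ~15% of mass in (0.3, 0.75)."""
    u = rng.random()
    if u < 0.475:
        return float(rng.beta(1.2, 8.0))
    if u < 0.95:
        return float(rng.beta(8.0, 1.2))
    return float(rng.uniform(0.3, 0.75))


def _map_interval(a: int, b: int, offset: int, locus_len: int, strand: str, chrom: str) -> GenomicInterval:
    if strand == "+":
        return GenomicInterval(chrom, offset + a, offset + b, "+")
    return GenomicInterval(chrom, offset + locus_len - b, offset + locus_len - a, "-")


@dataclass
class SyntheticDataset:
    """Emitted annotation plus truth tables; file writers for each artifact."""

    config: SimulationConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    truth_exons: pd.DataFrame
    truth_events: pd.DataFrame

    def write_gtf(self, path: str | Path) -> None:
        write_gtf(self.genes, path)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    @property
    def transcripts(self) -> dict[str, TranscriptModel]:
        return {
            t.transcript_id: t for g in self.genes for t in g.transcripts
        }


def _plant(seq: list[str], start: int, text: str) -> None:
    seq[start : start + len(text)] = list(text)


def _build_gene(
    idx: int,
    ctype: CodingType,
    sclass: SpliceClass,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chrom: str,
    offset: int,
) -> tuple[GeneModel, str, int, list[dict], dict | None]:
    """One templated gene; returns (gene, locus_seq, locus_len, truth rows, event)."""
    gid = f"GSYN{idx:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    L1 = int(rng.integers(80, 161))
    L3 = int(rng.integers(80, 161))
    L2 = max(30, int(round(cfg.medians[ctype] * np.exp(rng.normal(0.0, cfg.length_sigma)))))
    I1 = int(rng.integers(1100, 1601))
    I2 = int(rng.integers(1100, 1601))
    s2 = L1 + I1
    s3 = s2 + L2 + I2
    L = s3 + L3
    e1, e2, e3 = (0, L1), (s2, s2 + L2), (s3, s3 + L3)

    # CDS layout in transcript space, and the start-codon position
    if ctype is CodingType.TYPE1_5UTR:
        cds = [(s3 + 9, s3 + 39)]
        atg = s3 + 9
    elif ctype is CodingType.TYPE2_5UC:
        u = int(rng.integers(3, L2 - 6))
        c3 = 24 + (-(L2 - u)) % 3
        cds = [(s2 + u, s2 + L2), (s3, s3 + c3)]
        atg = s2 + u
    elif ctype is CodingType.TYPE3_CDS:
        c3 = 24 + (-(15 + L2)) % 3
        cds = [(L1 - 15, L1), (s2, s2 + L2), (s3, s3 + c3)]
        atg = L1 - 15
    elif ctype is CodingType.TYPE4_C3U:
        q0 = int(rng.integers(6, L2 - 3))
        q = q0 - (15 + q0) % 3
        if q < 3:
            q += 3
        cds = [(L1 - 15, L1), (s2, s2 + q)]
        atg = L1 - 15
    else:  # TYPE5_3UTR
        cds = [(9, 39)]
        atg = 9

    delta = 21
    tx_specs: list[tuple[str, list[tuple[int, int]], list[tuple[int, int]]]] = []
    tx_specs.append((f"{gid}_A", [e1, e2, e3], cds))
    focal_exons: list[tuple[tuple[int, int], str]] = [(e2, "A")]
    extra_acceptors: list[int] = []
    if sclass is SpliceClass.ASE:
        tx_specs.append((f"{gid}_B", [e1, e3], []))
    elif sclass is SpliceClass.SSE:
        e2v = (s2 - delta, s2 + L2)
        if ctype is CodingType.TYPE3_CDS:
            c3b = 24 + (-(15 + L2 + delta)) % 3
            cds_b = [(L1 - 15, L1), (s2 - delta, s2 + L2), (s3, s3 + c3b)]
        elif ctype is CodingType.TYPE4_C3U:
            cds_b = [(L1 - 15, L1), (s2 - delta, cds[1][1])]
        else:
            cds_b = list(cds)
        tx_specs.append((f"{gid}_B", [e1, e2v, e3], cds_b))
        focal_exons.append((e2v, "B"))
        extra_acceptors.append(s2 - delta)
    elif sclass is SpliceClass.OTHER_ALT:
        e2o = (s2 - 30, s2 + L2)
        tx_specs.append((f"{gid}_B", [e2o, e3], []))

    # locus sequence: random background with planted start codon and
    # GT/AG splice dinucleotides (transcript-space; reverse-complemented
    # as a whole for minus-strand genes)
    seq = list("".join(rng.choice(list("ACGT"), size=L)))
    for donor in (L1, s2 + L2):
        _plant(seq, donor, "GT")
    for acceptor in [s2, s3, *extra_acceptors]:
        _plant(seq, acceptor - 2, "AG")
    _plant(seq, atg, "ATG")
    locus = "".join(seq)
    if strand == "-":
        locus = revcomp(locus)

    transcripts = []
    for tid, exon_spans, cds_spans in tx_specs:
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                exons=[_map_interval(a, b, offset, L, strand, chrom) for a, b in exon_spans],
                cds=[_map_interval(a, b, offset, L, strand, chrom) for a, b in cds_spans],
            )
        )
    gene = GeneModel(
        gene_id=gid,
        gene_name=gid,
        chrom=chrom,
        strand=strand,
        transcripts=transcripts,
    )

    truth_rows = []
    for span, _iso in focal_exons:
        iv = _map_interval(span[0], span[1], offset, L, strand, chrom)
        truth_rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": strand,
                "coding_type": ctype.value,
                "splice_class": sclass.value,
            }
        )

    event = None
    if sclass is SpliceClass.ASE:
        ex = sorted(transcripts[0].exons, key=lambda e: e.start)
        a, b, c = ex
        event = {
            "event_id": f"{gid};SE:{chrom}:{a.end}-{b.start + 1}:{b.end}-{c.start + 1}:{strand}",
            "gene_id": gid,
            "chrom": chrom,
            "strand": strand,
            "exon_start": b.start,
            "exon_end": b.end,
            "up_junction": (chrom, a.end, b.start),
            "down_junction": (chrom, b.end, c.start),
            "skip_junction": (chrom, a.end, c.start),
            "inclusion_transcript": f"{gid}_A",
            "exclusion_transcript": f"{gid}_B",
            "coding_type": ctype.value,
        }
    return gene, locus, L, truth_rows, event


def simulate_annotation(config: SimulationConfig) -> SyntheticDataset:
    """Emit the planted annotation, genome sequence and truth tables."""
    rng = config.stream(_STREAM_ANNOTATION)
    chrom = "chrS1"
    gap = 2000
    offset = 1000
    genes: list[GeneModel] = []
    loci: list[str] = ["N" * offset]
    truth_rows: list[dict] = []
    events: list[dict] = []
    idx = 0
    for (ctype, sclass) in sorted(
        config.quotas, key=lambda k: (k[0].value, k[1].value)
    ):
        quota = config.quotas[(ctype, sclass)]
        per_gene = 2 if sclass is SpliceClass.SSE else 1
        for _ in range(quota // per_gene):
            gene, locus, locus_len, rows, event = _build_gene(
                idx, ctype, sclass, config, rng, chrom, offset
            )
            genes.append(gene)
            loci.append(locus)
            loci.append("".join(rng.choice(list("ACGT"), size=gap)))
            offset += locus_len + gap
            truth_rows.extend(rows)
            if event is not None:
                if config.psi_uniform is not None:
                    lo, hi = config.psi_uniform
                    event["true_psi"] = float(rng.uniform(lo, hi))
                else:
                    event["true_psi"] = _draw_psi(rng)
                event["bound"] = bool(rng.random() < config.bound_fraction)
                events.append(event)
            idx += 1
    truth_exons = pd.DataFrame(truth_rows)
    truth_events = pd.DataFrame(events)
    if not truth_events.empty:
        bound_map = dict(
            zip(
                truth_events.apply(
                    lambda r: (r.chrom, r.exon_start, r.exon_end, r.strand), axis=1
                ),
                truth_events.bound,
            )
        )
        truth_exons["bound"] = [
            bool(bound_map.get((r.chrom, r.start, r.end, r.strand), False))
            for r in truth_exons.itertuples()
        ]
    else:
        truth_exons["bound"] = False
    return SyntheticDataset(
        config=config,
        genes=genes,
        genome={chrom: "".join(loci)},
        truth_exons=truth_exons,
        truth_events=truth_events,
    )


# ---------------------------------------------------------------------------
# junction counts


def simulate_junction_counts(dataset: SyntheticDataset):
    """Binomial junction counts per sample around each event's true PSI.

    An included copy of the exon produces two inclusion junction reads'
    worth of evidence (upstream and downstream) while a skipped copy
    produces one skipping read, so for true PSI value psi the three
    junctions receive reads in proportion u : d : s = psi : psi : (1-psi).
    Per event and sample: total n ~ Poisson(depth), skipping reads
    s ~ Binomial(n, (1-psi)/(1+psi)), inclusion reads split evenly between
    the two inclusion junctions — under which the junction PSI estimator
    (u+d)/(u+d+2s) is consistent for psi.  Returns (samples, tissue_map).
    """
    from .splicing import JunctionCounts

    cfg = dataset.config
    rng = cfg.stream(_STREAM_JUNCTIONS)
    samples: list[JunctionCounts] = []
    tissue_map: dict[str, str] = {}
    events = dataset.truth_events
    for tissue, shift in cfg.tissues.items():
        for i in range(cfg.samples_per_tissue):
            sid = f"{tissue}_{i}"
            tissue_map[sid] = tissue
            counts: dict[tuple, int] = {}
            for ev in events.itertuples():
                psi_t = float(np.clip(ev.true_psi + shift, 0.0, 1.0))
                n = int(rng.poisson(cfg.depth))
                p_skip = (1.0 - psi_t) / (1.0 + psi_t)
                s = int(rng.binomial(n, p_skip)) if n else 0
                u = int(rng.binomial(n - s, 0.5)) if n - s else 0
                d = n - s - u
                counts[tuple(ev.up_junction)] = counts.get(tuple(ev.up_junction), 0) + u
                counts[tuple(ev.down_junction)] = counts.get(tuple(ev.down_junction), 0) + d
                counts[tuple(ev.skip_junction)] = counts.get(tuple(ev.skip_junction), 0) + s
            samples.append(JunctionCounts(sample_id=sid, counts=counts))
    return samples, tissue_map


# ---------------------------------------------------------------------------
# coverage


def coverage_for_exons(
    exons: Sequence[GenomicInterval],
    bound: Sequence[bool],
    rng: np.random.Generator,
    fold: float = 1.5,
    width: int = 500,
    lambda_bg: float = 8.0,
    bin_size: int = 10,
    flank: int = 600,
) -> CoverageTrack:
    """Poisson background coverage with fold-scaled upstream windows.

    Bins of ``bin_size`` nt span each exon's locus +/- ``flank``; for bound
    exons the bins inside the strand-aware upstream window
    (5' splice site - width .. 5' splice site) are drawn at fold * lambda.
    Loci of distinct exons must not overlap.
    """
    runs: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for exon, is_bound in zip(exons, bound):
        a = exon.start - flank
        b = exon.end + flank
        edges = np.arange(a, b + bin_size, bin_size, dtype=int)
        vals = rng.poisson(lambda_bg, size=len(edges) - 1).astype(float)
        if is_bound and fold != 1.0:
            if exon.strand == "+":
                w0, w1 = exon.start - width, exon.start
            else:
                w0, w1 = exon.end, exon.end + width
            inside = (edges[:-1] >= w0) & (edges[1:] <= w1)
            vals[inside] = rng.poisson(fold * lambda_bg, size=int(inside.sum()))
        runs.setdefault(exon.chrom, []).append((edges[:-1], edges[1:], vals))
    merged = {}
    for chrom, parts in runs.items():
        starts = np.concatenate([p[0] for p in parts])
        ends = np.concatenate([p[1] for p in parts])
        values = np.concatenate([p[2] for p in parts])
        merged[chrom] = (starts, ends, values)
    return CoverageTrack(merged)


def simulate_coverage(dataset: SyntheticDataset) -> tuple[CoverageTrack, pd.DataFrame]:
    """Coverage track over the dataset's cassette (event) exons.

    Bound exons carry the planted upstream enrichment; the returned frame
    lists the exons covered, with their bound flags.
    """
    cfg = dataset.config
    rng = cfg.stream(_STREAM_COVERAGE)
    ev = dataset.truth_events
    if ev.empty:
        raise ValueError("dataset has no skipping events to cover")
    exons = [
        GenomicInterval(r.chrom, r.exon_start, r.exon_end, r.strand)
        for r in ev.itertuples()
    ]
    track = coverage_for_exons(
        exons,
        list(ev.bound),
        rng,
        fold=cfg.fold,
        width=cfg.width,
        lambda_bg=cfg.lambda_bg,
        bin_size=cfg.cov_bin,
    )
    frame = pd.DataFrame(
        {
            "event_id": ev.event_id,
            "chrom": ev.chrom,
            "start": ev.exon_start,
            "end": ev.exon_end,
            "strand": ev.strand,
            "coding_type": ev.coding_type,
            "bound": ev.bound,
        }
    )
    return track, frame


def simulate_enrichment_pair(
    n_exons: int,
    fold: float,
    rng: np.random.Generator,
    width: int = 500,
    lambda_bg: float = 8.0,
    exon_len_median: int = 150,
) -> tuple[CoverageTrack, list[GenomicInterval], list[GenomicInterval]]:
    """Two exon sets on one track: set A upstream-enriched by ``fold``, set B not.

    A compact fixture for volcano-style enrichment studies; exon loci are
    spaced so coverage windows never overlap.
    """
    chrom = "chrE1"
    pos = 1000
    set_a: list[GenomicInterval] = []
    set_b: list[GenomicInterval] = []
    for group in ("a", "b"):
        for _ in range(n_exons):
            length = max(
                30, int(round(exon_len_median * np.exp(rng.normal(0.0, 0.3))))
            )
            start = pos + int(rng.integers(0, 9))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + length, strand)
            (set_a if group == "a" else set_b).append(iv)
            pos = start + length + 2400
    track = coverage_for_exons(
        set_a + set_b,
        [True] * n_exons + [False] * n_exons,
        rng,
        fold=fold,
        width=width,
        lambda_bg=lambda_bg,
    )
    return track, set_a, set_b


# ---------------------------------------------------------------------------
# knockdown


def simulate_knockdown(
    dataset: SyntheticDataset,
) -> tuple[dict[str, float], dict[str, float], pd.DataFrame]:
    """Control and knockdown TPM tables with planted dPSI effects.

    Bound events gain ``kd_effect`` PSI under knockdown (direct repression
    released by silencing); a ``kd_down_fraction`` of unbound events lose
    the same amount (indirect targets); the rest stay put.  Log-normal
    multiplicative noise with sigma ``noise_sigma`` is applied per isoform
    and condition.  Returns (ctrl_tpm, kd_tpm, truth) where truth records
    each event's planted dPSI.
    """
    cfg = dataset.config
    if not -1.0 <= cfg.kd_effect <= 1.0:
        raise ValueError("kd_effect must be in [-1, 1]")
    rng = cfg.stream(_STREAM_KNOCKDOWN)
    ctrl: dict[str, float] = {}
    kd: dict[str, float] = {}
    rows = []
    for ev in dataset.truth_events.itertuples():
        psi = float(ev.true_psi)
        if ev.bound:
            psi_kd = float(np.clip(psi + cfg.kd_effect, 0.0, 1.0))
        elif rng.random() < cfg.kd_down_fraction:
            psi_kd = float(np.clip(psi - cfg.kd_effect, 0.0, 1.0))
        else:
            psi_kd = psi
        for cond, p, table in (("ctrl", psi, ctrl), ("kd", psi_kd, kd)):
            noise_inc = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
            noise_exc = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
            table[ev.inclusion_transcript] = cfg.total_tpm * p * noise_inc
            table[ev.exclusion_transcript] = cfg.total_tpm * (1.0 - p) * noise_exc
        rows.append(
            {
                "event_id": ev.event_id,
                "bound": bool(ev.bound),
                "true_psi_ctrl": psi,
                "true_psi_kd": psi_kd,
                "planted_dpsi": psi_kd - psi,
            }
        )
    return ctrl, kd, pd.DataFrame(rows)


def write_tpm_tsv(tpms: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tTPM\n")
        for tid in sorted(tpms):
            fh.write(f"{tid}\t{tpms[tid]:.6f}\n")


def read_tpm_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


# ---------------------------------------------------------------------------
# species sets


def simulate_species_sets(
    config: SimulationConfig,
) -> tuple[dict[str, set[str]], dict[tuple[str, str], dict[str, set[str]]], str]:
    """Gene sets inherited down the planted tree with per-branch loss.

    An ancestral pool of ``pool_size`` genes is carried from the root; on a
    branch of length L each gene survives independently with probability
    (1 - loss_rate)**L (L defaults to 1 when the tree has no lengths).
    Ortholog maps are identity on genes shared by a species pair.
    Returns (sets, maps, planted_newick).
    """
    rng = config.stream(_STREAM_SPECIES)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    if len(tree.leaf_nodes()) < 3:
        raise ValueError("planted tree needs >= 3 leaves")
    pool = [f"g{i:04d}" for i in range(config.pool_size)]
    tree.seed_node.gene_set = set(pool)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_set = node.parent_node.gene_set
        length = node.edge.length if node.edge.length is not None else 1.0
        survive = (1.0 - config.loss_rate) ** length
        keep = rng.random(len(pool)) < survive
        node.gene_set = {
            g for g, k in zip(pool, keep) if k and g in parent_set
        }
    sets = {
        leaf.taxon.label: leaf.gene_set for leaf in tree.leaf_node_iter()
    }
    maps: dict[tuple[str, str], dict[str, set[str]]] = {}
    species = sorted(sets)
    for a in species:
        for b in species:
            if a == b:
                continue
            shared = sets[a] & sets[b]
            maps[(a, b)] = {g: {g} for g in shared}
    return sets, maps, config.tree


def write_ortholog_tsvs(
    maps: Mapping[tuple[str, str], Mapping[str, set[str]]], path: str | Path
) -> None:
    """All pairwise maps into a single 4-column TSV (unordered pairs once)."""
    with open(path, "w") as fh:
        for (a, b) in sorted(maps):
            if a >= b:
                continue
            for g in sorted(maps[(a, b)]):
                for h in sorted(maps[(a, b)][g]):
                    fh.write(f"{a}\t{g}\t{b}\t{h}\n")
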