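"""Cassette-exon (skipped-exon) events and PSI quantification.

An SE event pairs two inclusion junctions (upstream flank -> exon,
exon -> downstream flank) with the skipping junction that joins the flanks
directly.  Junction-based PSI uses

    PSI = (u + d) / (u + d + 2 s)

where u/d/s are upstream-inclusion, downstream-inclusion and skipping
junction read counts, with the value reported as missing unless
u + d + s exceeds a read-count threshold (default 50, strictly greater).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ClassifiedExon, GeneModel, GenomicInterval

#: junction key: (chrom, donor_end, acceptor_start), 0-based half-open intron
JunctionKey = tuple[str, int, int]


@dataclass(frozen=True)
class SkippingEvent:
    event_id: str
    gene_id: str
    skipped_exon: GenomicInterval
    upstream_junction: JunctionKey
    downstream_junction: JunctionKey
    skipping_junction: JunctionKey
    inclusion_transcripts: tuple[str, ...]
    exclusion_transcripts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.skipping_junction[1] != self.upstream_junction[1]:
            raise ValueError("skipping junction donor must match upstream donor")
        if self.skipping_junction[2] != self.downstream_junction[2]:
            raise ValueError("skipping junction acceptor must match downstream acceptor")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError("event needs inclusion and exclusion transcripts")


@dataclass
class JunctionCounts:
    """Per-sample junction read counts keyed by (chrom, donor, acceptor)."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative junction count for {key}")

    def get(self, key: JunctionKey) -> int:
        return self.counts.get(key, 0)


@dataclass
class PsiValue:
    value: float  # NaN when the threshold fails
    u: int
    d: int
    s: int

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.value)


def generate_se_events(genes: Iterable[GeneModel]) -> list[SkippingEvent]:
    """Enumerate skipped-exon events: one per (gene, exon, flank pair).

    For each transcript triple of genomically adjacent exons A-B-C, an event
    exists when another isoform of the gene splices A directly to C with the
    identical donor and acceptor.  Event IDs follow the SUPPA SE convention
    (1-based coordinates): ``gene;SE:chrom:Aend-Bstart:Bend-Cstart:strand``.
    """
    events: list[SkippingEvent] = []
    for gene in genes:
        tx_junctions = {
            t.transcript_id: set(t.junctions()) for t in gene.transcripts
        }
        seen: set[tuple] = set()
        for t in gene.transcripts:
            ex = sorted(t.exons, key=lambda e: e.start)
            for a, b, c in zip(ex, ex[1:], ex[2:]):
                key = (a.end, b.start, b.end, c.start)
                if key in seen:
                    continue
                skip = (a.end, c.start)
                exclusion = sorted(
                    tid for tid, js in tx_junctions.items() if skip in js
                )
                if not exclusion:
                    continue
                inclusion = sorted(
                    tid
                    for tid, js in tx_junctions.items()
                    if (a.end, b.start) in js and (b.end, c.start) in js
                )
                seen.add(key)
                chrom = gene.chrom
                event_id = (
                    f"{gene.gene_id};SE:{chrom}:{a.end}-{b.start + 1}:"
                    f"{b.end}-{c.start + 1}:{gene.strand}"
                )
                events.append(
                    SkippingEvent(
                        event_id=event_id,
                        gene_id=gene.gene_id,
                        skipped_exon=b,
                        upstream_junction=(chrom, a.end, b.start),
                        downstream_junction=(chrom, b.end, c.start),
                        skipping_junction=(chrom, a.end, c.start),
                        inclusion_transcripts=tuple(inclusion),
                        exclusion_transcripts=tuple(exclusion),
                    )
                )
    return events


def label_events(
    events: Sequence[SkippingEvent], classified: Sequence[ClassifiedExon]
) -> pd.DataFrame:
    """Attach the skipped exon's coding type/splice class to each event."""
    lookup = {e.interval.coords(): e for e in classified}
    rows = []
    for ev in events:
        ce = lookup.get(ev.skipped_exon.coords())
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "coding_type": ce.coding_type.value if ce else None,
                "splice_class": ce.splice_class.value if ce else None,
                "is_5uc_event": bool(ce and ce.coding_type.value == "Type2"),
            }
        )
    return pd.DataFrame(rows)


def events_to_ioe(events: Sequence[SkippingEvent], path: str | Path) -> None:
    """Write events in SUPPA-compatible ioe layout."""
    with open(path, "w") as fh:
        fh.write("seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n")
        for ev in events:
            total = sorted(set(ev.inclusion_transcripts) | set(ev.exclusion_transcripts))
            fh.write(
                f"{ev.skipped_exon.chrom}\t{ev.gene_id}\t{ev.event_id}\t"
                f"{','.join(ev.inclusion_transcripts)}\t{','.join(total)}\n"
            )


def compute_psi(
    event: SkippingEvent, junctions: JunctionCounts, min_total: int = 50
) -> PsiValue:
    """Junction-based PSI; missing (NaN) unless u + d + s > ``min_total``."""
    u = junctions.get(event.upstream_junction)
    d = junctions.get(event.downstream_junction)
    s = junctions.get(event.skipping_junction)
    if min(u, d, s) < 0:
        raise ValueError("negative junction counts")
    if u + d + s <= min_total:
        return PsiValue(value=float("nan"), u=u, d=d, s=s)
    return PsiValue(value=(u + d) / (u + d + 2 * s), u=u, d=d, s=s)


def psi_from_tpm(
    event: SkippingEvent, transcript_tpms: Mapping[str, float]
) -> float:
    """Isoform-abundance PSI: sum(inclusion TPM) / sum(all event TPM).

    Absent transcripts count as 0 TPM; a zero denominator gives NaN.
    """
    for tid, tpm in transcript_tpms.items():
        if tpm < 0:
            raise ValueError(f"negative TPM for {tid}")
    inc = sum(transcript_tpms.get(t, 0.0) for t in event.inclusion_transcripts)
    exc = sum(transcript_tpms.get(t, 0.0) for t in event.exclusion_transcripts)
    denom = inc + exc
    if denom == 0:
        return float("nan")
    return inc / denom


def sample_psi_matrix(
    events: Sequence[SkippingEvent],
    samples: Sequence[JunctionCounts],
    min_total: int = 50,
) -> pd.DataFrame:
    """Events x samples PSI matrix (NaN where the read threshold fails)."""
    data = {
        s.sample_id: [compute_psi(ev, s, min_total).value for ev in events]
        for s in samples
    }
    return pd.DataFrame(data, index=[ev.event_id for ev in events])


def tissue_psi_matrix(
    events: Sequence[SkippingEvent],
    samples: Sequence[JunctionCounts],
    tissue_map: Mapping[str, str],
    min_total: int = 50,
) -> pd.DataFrame:
    """Events x tissues PSI: per-tissue median over each sample's PSI.

    A tissue is NaN for an event when every sample fails the threshold.
    """
    by_sample = sample_psi_matrix(events, samples, min_total)
    missing = set(tissue_map) - set(by_sample.columns)
    if missing:
        raise KeyError(f"samples in tissue_map absent from counts: {sorted(missing)}")
    tissues = pd.Series({s: tissue_map[s] for s in by_sample.columns})
    return by_sample.T.groupby(tissues).median().T


def tissue_delta_psi(matrix: pd.DataFrame, min_tissues: int = 3) -> pd.DataFrame:
    """Per-(event, tissue) deviation from the event's cross-tissue median.

    Events with fewer than ``min_tissues`` non-missing tissue values are
    excluded.
    """
    keep = matrix.notna().sum(axis=1) >= min_tissues
    m = matrix.loc[keep]
    return m.sub(m.median(axis=1), axis=0)


def moderate_fraction(
    tissue_psis: Sequence[float], lo: float = 0.3, hi: float = 0.75
) -> float:
    """Fraction of non-missing PSIs strictly inside (lo, hi); NaN if all missing."""
    vals = np.asarray(tissue_psis, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(((vals > lo) & (vals < hi)).mean())


def delta_psi_condition(
    psi_kd: float, psi_ctrl: float, band: float = 0.2
) -> tuple[float, str]:
    """Knockdown-minus-control dPSI and its group label.

    Bands: UP (dPSI >= band), DOWN (dPSI <= -band), NEUTRAL in between;
    boundaries belong to UP/DOWN.  Events with a missing PSI on either side
    raise; callers should exclude them beforehand.
    """
    if not (np.isfinite(psi_kd) and np.isfinite(psi_ctrl)):
        raise ValueError("both PSIs must be non-missing")
    dpsi = psi_kd - psi_ctrl
    if dpsi >= band:
        label = "UP"
    elif dpsi <= -band:
        label = "DOWN"
    else:
        label = "NEUTRAL"
    return dpsi, label


def read_junction_gct(path: str | Path) -> list[JunctionCounts]:
    """Read a GCT-like junction count table into per-sample JunctionCounts.

    Leading '#...' and dimension header lines are tolerated. The first
    column holds GTEx-style junction IDs ``chrom_start_end`` with 1-based
    inclusive intron coordinates (converted to half-open on read); an
    optional second 'Description' column is ignored.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    for i, line in enumerate(lines):
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#") or (len(fields) <= 2 and not line.startswith("Name")):
            start = i + 1
            continue
        break
    df = pd.read_csv(path, sep="\t", skiprows=start)
    id_col = df.columns[0]
    sample_cols = [c for c in df.columns[1:] if c != "Description"]
    keys: list[JunctionKey] = []
    for jid in df[id_col]:
        chrom, s, e = str(jid).rsplit("_", 2)
        keys.append((chrom, int(s) - 1, int(e)))
    out = []
    for col in sample_cols:
        vals = df[col].to_numpy()
        out.append(
            JunctionCounts(
                sample_id=str(col),
                counts={k: int(v) for k, v in zip(keys, vals)},
            )
        )
    return out


def write_junction_gct(
    samples: Sequence[JunctionCounts], path: str | Path
) -> None:
    """Write junction counts as a GCT-like TSV (GTEx-style junction IDs)."""
    all_keys = sorted({k for s in samples for k in s.counts})
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(all_keys)}\t{len(samples)}\n")
        fh.write("Name\tDescription\t" + "\t".join(s.sample_id for s in samples) + "\n")
        for key in all_keys:
            chrom, s0, e0 = key
            jid = f"{chrom}_{s0 + 1}_{e0}"
            row = "\t".join(str(s.get(key)) for s in samples)
            fh.write(f"{jid}\tjunction\t{row}\n")
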