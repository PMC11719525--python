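"""Per-class exon length distributions and in-frame codon usage.

Length summaries follow boxplot conventions (median, quartiles, whiskers at
1.5 x IQR).  Codon usage counts complete in-frame codons whose three bases
all lie in the exon's CDS portion, with the reading frame taken from a
representative containing transcript (the one with the longest annotated
CDS); codons split across a splice junction are excluded.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import ClassifiedExon, CodingType, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(source, chrom: str, start: int, end: int) -> str:
    """0-based half-open sequence fetch from a pyfaidx Fasta or dict of str."""
    return str(source[chrom][start:end]).upper()


def _box_stats(lengths: np.ndarray) -> dict:
    if lengths.size == 0:
        return {
            "n": 0,
            "median": np.nan,
            "q1": np.nan,
            "q3": np.nan,
            "whisker_lo": np.nan,
            "whisker_hi": np.nan,
        }
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    iqr = q3 - q1
    in_fence = lengths[(lengths >= q1 - 1.5 * iqr) & (lengths <= q3 + 1.5 * iqr)]
    return {
        "n": int(lengths.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(in_fence.min()),
        "whisker_hi": float(in_fence.max()),
    }


def length_stats(
    classified: Iterable[ClassifiedExon], group_by: str = "coding_type"
) -> pd.DataFrame:
    """Boxplot-style exon length summaries per group, plus an 'all' row.

    ``group_by`` is ``"coding_type"`` or ``"splice_class:coding_type"``.
    Lengths are end - start in nt.
    """
    if group_by not in ("coding_type", "splice_class:coding_type"):
        raise ValueError(f"unknown group_by {group_by!r}")
    exons = list(classified)
    lengths = np.array([e.length for e in exons], dtype=float)

    def key(e: ClassifiedExon) -> str:
        if group_by == "coding_type":
            return e.coding_type.value
        return f"{e.splice_class.value}:{e.coding_type.value}"

    rows = {"all": _box_stats(lengths)}
    groups: dict[str, list[float]] = {}
    for e in exons:
        groups.setdefault(key(e), []).append(e.length)
    for name in sorted(groups):
        rows[name] = _box_stats(np.array(groups[name], dtype=float))
    return pd.DataFrame(rows).T.rename_axis("group")


def representative_transcript(
    exon: ClassifiedExon, transcripts: Mapping[str, TranscriptModel]
) -> TranscriptModel | None:
    """Containing transcript with the longest CDS (ties by transcript_id)."""
    candidates = [
        transcripts[t]
        for t in exon.containing_transcripts
        if t in transcripts and transcripts[t].is_coding
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (-t.cds_length, t.transcript_id))


def exon_codon_counts(
    exon: ClassifiedExon,
    transcript: TranscriptModel,
    sequence,
) -> Counter:
    """In-frame codons fully inside the exon's CDS portion of ``transcript``.

    The CDS sequence is assembled in transcript orientation (segments
    reverse-complemented on the minus strand); codon i is counted iff all
    three of its bases map into CDS segments contained in the exon.
    """
    cds_seq_parts: list[str] = []
    exon_mask_parts: list[np.ndarray] = []
    for seg in transcript.cds:  # transcript order
        raw = _fetch(sequence, seg.chrom, seg.start, seg.end)
        if transcript.strand == "-":
            raw = revcomp(raw)
        cds_seq_parts.append(raw)
        inside = exon.interval.contains(seg)
        exon_mask_parts.append(np.full(len(raw), inside))
    cds_seq = "".join(cds_seq_parts)
    mask = (
        np.concatenate(exon_mask_parts)
        if exon_mask_parts
        else np.zeros(0, dtype=bool)
    )
    counts: Counter = Counter()
    for i in range(len(cds_seq) // 3):
        if mask[3 * i : 3 * i + 3].all():
            codon = cds_seq[3 * i : 3 * i + 3]
            if set(codon) <= set(BASES):
                counts[codon] += 1
    return counts


def codon_usage(
    classified: Iterable[ClassifiedExon],
    transcripts: Mapping[str, TranscriptModel],
    sequence,
) -> pd.DataFrame:
    """Pooled 64-codon counts and frequencies per coding type.

    Returns a tidy frame (coding_type, codon, count, frequency); frequencies
    are normalised to sum to 1 over the pooled counts of each type. Exons
    without a coding representative transcript (e.g. pure-UTR types)
    contribute nothing.
    """
    pooled: dict[str, Counter] = {t.value: Counter() for t in CodingType}
    for exon in classified:
        rep = representative_transcript(exon, transcripts)
        if rep is None:
            continue
        pooled[exon.coding_type.value] += exon_codon_counts(exon, rep, sequence)
    rows = []
    for ctype, counter in pooled.items():
        total = sum(counter.values())
        for codon in ALL_CODONS:
            n = counter.get(codon, 0)
            rows.append(
                {
                    "coding_type": ctype,
                    "codon": codon,
                    "count": n,
                    "frequency": n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
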