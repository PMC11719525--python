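"""Strand-aware meta-coverage matrices and region-wise enrichment testing.

Coverage is consumed as step functions (bedGraph-style intervals per
chromosome).  Around each exon a 110-column profile is built: 50 upstream
10-nt bins, 10 body bins (the exon rescaled to a fixed 100-nt body) and 50
downstream bins, oriented 5'->3' on the exon's strand.  Region enrichment
between two exon sets compares the per-bin median profiles by median
fold-change and the exact Wilcoxon signed-rank test; the conventional
volcano cutoff is log2 FC > 0.4 and -log10 p > 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GenomicInterval
from .stats import GroupTestResult, exact_wilcoxon_signed_rank, steel_dwass

REGIONS = ("UPSTREAM", "EXON", "DOWNSTREAM")


class CoverageTrack:
    """Non-negative step-function coverage per chromosome.

    Stores sorted, non-overlapping (start, end, value) runs and answers
    mean-signal queries over arbitrary (possibly fractional) windows through
    the cumulative integral of the signal; positions outside any run have
    signal 0.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=float)
            ends = np.asarray(ends, dtype=float)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise ValueError(f"negative coverage on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage runs on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._runs[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        runs = {
            chrom: (
                grp["start"].to_numpy(float),
                grp["end"].to_numpy(float),
                grp["value"].to_numpy(float),
            )
            for chrom, grp in df.groupby("chrom", sort=True)
        }
        return cls(runs)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                starts, ends, values, _ = self._runs[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def _integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Cumulative signal integral from -inf to each position in x."""
        starts, ends, values, cum = self._runs[chrom]
        idx = np.searchsorted(starts, x, side="right") - 1
        out = np.zeros_like(x, dtype=float)
        valid = idx >= 0
        iv = idx[valid]
        inside = np.minimum(x[valid], ends[iv]) - starts[iv]
        inside = np.clip(inside, 0.0, None)
        out[valid] = cum[iv] + values[iv] * inside
        return out

    def binned_mean(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal in each bin delimited by ``edges`` (len k+1 -> k means)."""
        if chrom not in self._runs:
            raise KeyError(chrom)
        edges = np.asarray(edges, dtype=float)
        integ = self._integral(chrom, edges)
        widths = np.diff(edges)
        return np.diff(integ) / widths


@dataclass
class CoverageMatrix:
    """Exons x bins meta-coverage matrix, columns 5'->3' of each exon."""

    values: np.ndarray  # shape (n_exons, n_up + n_body + n_down)
    exons: list[GenomicInterval]
    up: int
    body: int
    down: int
    bin_size: int

    @property
    def n_up(self) -> int:
        return self.up // self.bin_size

    @property
    def n_body(self) -> int:
        return self.body // self.bin_size

    def region_columns(self, region: str) -> slice:
        nu, nb = self.n_up, self.n_body
        if region == "UPSTREAM":
            return slice(0, nu)
        if region == "EXON":
            return slice(nu, nu + nb)
        if region == "DOWNSTREAM":
            return slice(nu + nb, self.values.shape[1])
        raise ValueError(f"unknown region {region!r}")

    def to_frame(self) -> pd.DataFrame:
        names = [f"{e.chrom}:{e.start}-{e.end}({e.strand})" for e in self.exons]
        return pd.DataFrame(self.values, index=names)


def build_coverage_matrix(
    track: CoverageTrack,
    exons: Sequence[GenomicInterval],
    up: int = 500,
    body: int = 100,
    down: int = 500,
    bin_size: int = 10,
    skip_zeros: bool = True,
) -> CoverageMatrix:
    """Meta-coverage matrix around an exon set.

    The exon body is rescaled to ``body`` nt by length-weighted averaging
    into ``body/bin_size`` bins; flanks use fixed ``bin_size`` bins. Rows are
    column-reversed on the minus strand so column 0 is always 5'-most.
    All-zero rows are dropped (skipZeros semantics), as are exons on
    chromosomes absent from the track.
    """
    if up % bin_size or down % bin_size or body % bin_size:
        raise ValueError("bin_size must divide up, body and down lengths")
    rows = []
    kept = []
    for exon in exons:
        if exon.chrom not in track.chroms:
            continue
        up_edges = np.arange(exon.start - up, exon.start + 1, bin_size, dtype=float)
        body_edges = np.linspace(exon.start, exon.end, body // bin_size + 1)
        down_edges = np.arange(exon.end, exon.end + down + 1, bin_size, dtype=float)
        row = np.concatenate(
            [
                track.binned_mean(exon.chrom, up_edges),
                track.binned_mean(exon.chrom, body_edges),
                track.binned_mean(exon.chrom, down_edges),
            ]
        )
        if exon.strand == "-":
            row = row[::-1]
        if skip_zeros and not np.any(row):
            continue
        rows.append(row)
        kept.append(exon)
    n_cols = (up + down + body) // bin_size
    values = np.vstack(rows) if rows else np.zeros((0, n_cols))
    return CoverageMatrix(
        values=values, exons=kept, up=up, body=body, down=down, bin_size=bin_size
    )


@dataclass
class RegionComparison:
    region: str
    log2_fc: float
    p_value: float
    n_bins: int
    passes_cutoff: bool
    method: str


def region_enrichment(
    matrix_a: CoverageMatrix,
    matrix_b: CoverageMatrix,
    region: str,
    fc_cutoff: float = 0.4,
    neglog10p_cutoff: float = 6.0,
    ratio_of_medians: bool = False,
) -> RegionComparison:
    """Enrichment of set A over set B within one region.

    Per-bin median profiles over each matrix's rows are paired by bin;
    log2 FC is the log2 of the median per-bin ratio (zero-denominator bins
    excluded; ``ratio_of_medians`` switches to median(a)/median(b)), and the
    p-value comes from the exact Wilcoxon signed-rank test on the paired
    profiles.
    """
    if (matrix_a.up, matrix_a.body, matrix_a.down, matrix_a.bin_size) != (
        matrix_b.up,
        matrix_b.body,
        matrix_b.down,
        matrix_b.bin_size,
    ):
        raise ValueError("matrices built with different window parameters")
    cols = matrix_a.region_columns(region)
    prof_a = np.median(matrix_a.values[:, cols], axis=0)
    prof_b = np.median(matrix_b.values[:, cols], axis=0)
    ok = prof_b > 0
    if not np.any(ok):
        raise ValueError(f"region {region}: no bins with nonzero denominator")
    if ratio_of_medians:
        fc = float(np.median(prof_a[ok]) / np.median(prof_b[ok]))
    else:
        fc = float(np.median(prof_a[ok] / prof_b[ok]))
    log2_fc = float(np.log2(fc)) if fc > 0 else float("-inf")
    res = exact_wilcoxon_signed_rank(prof_a, prof_b)
    passes = log2_fc > fc_cutoff and -np.log10(max(res.p_value, 1e-300)) > neglog10p_cutoff
    return RegionComparison(
        region=region,
        log2_fc=log2_fc,
        p_value=res.p_value,
        n_bins=int(prof_a.size),
        passes_cutoff=bool(passes),
        method=res.method,
    )


def volcano_table(
    matrix_a: CoverageMatrix, matrix_b: CoverageMatrix, factor: str = "factor"
) -> pd.DataFrame:
    """Region-wise enrichment rows (factor x region x log2FC x p) for plotting."""
    rows = []
    for region in REGIONS:
        cmp_ = region_enrichment(matrix_a, matrix_b, region)
        rows.append(
            {
                "factor": factor,
                "region": region,
                "log2_fc": cmp_.log2_fc,
                "p_value": cmp_.p_value,
                "neg_log10_p": -np.log10(max(cmp_.p_value, 1e-300)),
                "passes_cutoff": cmp_.passes_cutoff,
            }
        )
    return pd.DataFrame(rows)


def stratified_upstream_coverage(
    matrix: CoverageMatrix,
    groups: Mapping[GenomicInterval, str],
    bin_nt: int = 50,
    min_group: int = 2,
) -> tuple[GroupTestResult, pd.DataFrame]:
    """Compare upstream binding across dPSI groups (Steel-Dwass).

    The 500-nt upstream window is re-binned to ``bin_nt`` bins per exon; each
    exon contributes the median of its re-binned values as one observation
    to its group.  Returns the all-pairs test result and a tidy frame of
    per-group per-bin medians for boxplot display. Groups with fewer than
    ``min_group`` exons are excluded.
    """
    factor = bin_nt // matrix.bin_size
    nu = matrix.n_up
    if nu % factor:
        raise ValueError("bin_nt must be a multiple of the matrix bin size")
    upstream = matrix.values[:, :nu]
    rebinned = upstream.reshape(upstream.shape[0], nu // factor, factor).mean(axis=2)
    per_group: dict[str, list[np.ndarray]] = {}
    for i, exon in enumerate(matrix.exons):
        label = groups.get(exon)
        if label is None:
            continue
        per_group.setdefault(label, []).append(rebinned[i])
    per_group = {
        k: v for k, v in per_group.items() if len(v) >= min_group
    }
    if len(per_group) < 2:
        raise ValueError("need >= 2 groups with enough exons")
    labels = sorted(per_group)
    samples = [
        np.median(np.vstack(per_group[lab]), axis=1) for lab in labels
    ]  # one value per exon
    result = steel_dwass(samples, labels=labels)
    box_rows = []
    for lab in labels:
        bin_medians = np.median(np.vstack(per_group[lab]), axis=0)
        for b, v in enumerate(bin_medians):
            box_rows.append({"group": lab, "bin": b, "median_coverage": float(v)})
    return result, pd.DataFrame(box_rows)
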