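"""End-to-end orchestration: classify -> features -> events/PSI -> coverage -> evolution.

``run_full`` executes whatever stages the configured inputs allow, skipping
stages whose inputs are absent, and writes versioned TSV outputs plus a JSON
manifest of every parameter used.  Stage outputs are pure functions of the
inputs and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__
from .annotation import filter_swissprot, read_gtf
from .classify import classified_to_frame, classify_all
from .coverage import CoverageTrack, build_coverage_matrix, volcano_table
from .features import codon_usage, length_stats
from .splicing import (
    delta_psi_condition,
    events_to_ioe,
    generate_se_events,
    label_events,
    psi_from_tpm,
    read_junction_gct,
    tissue_delta_psi,
    tissue_psi_matrix,
)
from .simulate import read_tpm_tsv


@dataclass
class RunConfig:
    """Input paths and analysis thresholds (defaults are the standard settings)."""

    gtf: str | None = None
    swissprot: str | None = None
    fasta: str | None = None
    junctions: str | None = None
    tissue_map: str | None = None
    tpm_ctrl: str | None = None
    tpm_kd: str | None = None
    track: str | None = None
    out_dir: str = "exon5uc_out"
    seed: int = 0
    min_total: int = 50
    psi_lo: float = 0.3
    psi_hi: float = 0.75
    dpsi_band: float = 0.2
    fc_cutoff: float = 0.4
    neglog10p_cutoff: float = 6.0
    up: int = 500
    body: int = 100
    down: int = 500
    bin_size: int = 10

    def validate(self) -> None:
        if not 0 <= self.psi_lo < self.psi_hi <= 1:
            raise ValueError("PSI band must satisfy 0 <= lo < hi <= 1")
        if not 0 < self.dpsi_band <= 1:
            raise ValueError("dPSI band must be in (0, 1]")
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")


def run_full(config: RunConfig) -> dict:
    """Run all stages whose inputs are present; returns a report dict.

    Outputs under ``config.out_dir``: classified exon TSV, the coding-type x
    splice-class summary, length summaries, codon tables (when a FASTA is
    given), ioe events, PSI / tissue-dPSI matrices (when junction counts are
    given), condition dPSI groups (when control/knockdown TPMs are given),
    and the volcano table (when a coverage track is given).
    """
    config.validate()
    if config.gtf is None:
        raise ValueError("a GTF annotation is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "version": __version__}

    genes = read_gtf(config.gtf)
    if config.swissprot:
        genes = filter_swissprot(genes, config.swissprot)
    classified, summary = classify_all(genes)
    cf = classified_to_frame(classified)
    cf.to_csv(out / "classified_exons.tsv", sep="\t", index=False)
    summary.to_tsv(out / "classification_summary.tsv")
    report["stages"].append("classify")
    report["n_genes"] = len(genes)
    report["n_internal_exons"] = len(classified)
    report["summary"] = summary.with_totals().to_dict()

    length_stats(classified).to_csv(out / "length_stats.tsv", sep="\t")
    if config.fasta:
        transcripts = {t.transcript_id: t for g in genes for t in g.transcripts}
        usage = codon_usage(classified, transcripts, pyfaidx.Fasta(config.fasta))
        usage.to_csv(out / "codon_usage.tsv", sep="\t", index=False)
        report["stages"].append("features")

    events = generate_se_events(genes)
    events_to_ioe(events, out / "events.ioe")
    labels = label_events(events, classified)
    labels.to_csv(out / "event_labels.tsv", sep="\t", index=False)
    report["stages"].append("events")
    report["n_se_events"] = len(events)
    report["n_5uc_events"] = int(labels.is_5uc_event.sum())

    if config.junctions and config.tissue_map:
        samples = read_junction_gct(config.junctions)
        tmap = (
            pd.read_csv(config.tissue_map, sep="\t", index_col=0)
            .iloc[:, 0]
            .to_dict()
        )
        psi = tissue_psi_matrix(events, samples, tmap, config.min_total)
        psi.to_csv(out / "tissue_psi.tsv", sep="\t")
        dpsi = tissue_delta_psi(psi)
        dpsi.to_csv(out / "tissue_delta_psi.tsv", sep="\t")
        report["stages"].append("psi")

    if config.tpm_ctrl and config.tpm_kd:
        ctrl = read_tpm_tsv(config.tpm_ctrl)
        kd = read_tpm_tsv(config.tpm_kd)
        rows = []
        for ev in events:
            p_ctrl = psi_from_tpm(ev, ctrl)
            p_kd = psi_from_tpm(ev, kd)
            if not (np.isfinite(p_ctrl) and np.isfinite(p_kd)):
                continue
            dpsi_val, group = delta_psi_condition(p_kd, p_ctrl, config.dpsi_band)
            rows.append(
                {
                    "event_id": ev.event_id,
                    "psi_ctrl": p_ctrl,
                    "psi_kd": p_kd,
                    "dpsi": dpsi_val,
                    "group": group,
                }
            )
        pd.DataFrame(rows).to_csv(out / "condition_dpsi.tsv", sep="\t", index=False)
        report["stages"].append("dpsi")

    if config.track:
        track = CoverageTrack.from_bedgraph(config.track)
        ase_2 = [
            e.interval
            for e in classified
            if e.coding_type.value == "Type2" and e.splice_class.value == "ASE"
        ]
        ase_3 = [
            e.interval
            for e in classified
            if e.coding_type.value == "Type3" and e.splice_class.value == "ASE"
        ]
        if ase_2 and ase_3:
            mat_a = build_coverage_matrix(
                track, ase_2, config.up, config.body, config.down, config.bin_size
            )
            mat_b = build_coverage_matrix(
                track, ase_3, config.up, config.body, config.down, config.bin_size
            )
            volcano = volcano_table(mat_a, mat_b)
            volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
            report["stages"].append("coverage")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"config": asdict(config), "report": report}, fh, indent=2, default=str)
    return report
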