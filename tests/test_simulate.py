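"""Synthetic-data generator: determinism, truth consistency, edge cases."""

import numpy as np
import pytest

from exon5uc.annotation import read_gtf
from exon5uc.models import CodingType, GenomicInterval, SpliceClass
from exon5uc.simulate import (
    SimulationConfig,
    coverage_for_exons,
    simulate_annotation,
    simulate_coverage,
    simulate_junction_counts,
    simulate_knockdown,
    simulate_species_sets,
)
from exon5uc.splicing import generate_se_events


def only(ctype, sclass, n):
    quotas = {(ct, sc): 0 for ct in CodingType for sc in SpliceClass}
    quotas[(ctype, sclass)] = n
    return quotas


class TestAnnotation:
    def test_emitted_gtf_parses_and_matches_model(self, sim_dataset, tmp_path):
        p = tmp_path / "a.gtf"
        sim_dataset.write_gtf(p)
        genes = read_gtf(p)
        assert len(genes) == len(sim_dataset.genes)

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        for sub in ("r1", "r2"):
            d = tmp_path / sub
            d.mkdir()
            ds = simulate_annotation(SimulationConfig(seed=42))
            ds.write_gtf(d / "a.gtf")
            ds.write_fasta(d / "g.fa")
        assert (tmp_path / "r1/a.gtf").read_bytes() == (tmp_path / "r2/a.gtf").read_bytes()
        assert (tmp_path / "r1/g.fa").read_bytes() == (tmp_path / "r2/g.fa").read_bytes()

    def test_quota_of_type2_ases(self):
        ds = simulate_annotation(
            SimulationConfig(seed=0, quotas=only(CodingType.TYPE2_5UC, SpliceClass.ASE, 10))
        )
        assert len(ds.genes) == 10
        assert len(ds.truth_events) == 10
        assert (ds.truth_exons.coding_type == "Type2").all()

    def test_odd_sse_quota_is_infeasible(self):
        with pytest.raises(ValueError, match="SSE"):
            SimulationConfig(seed=0, quotas=only(CodingType.TYPE3_CDS, SpliceClass.SSE, 7))

    def test_kd_effect_bounds_validated(self):
        with pytest.raises(ValueError, match="kd_effect"):
            SimulationConfig(seed=0, kd_effect=1.5)

    def test_genome_has_planted_start_codon(self):
        ds = simulate_annotation(
            SimulationConfig(seed=1, quotas=only(CodingType.TYPE2_5UC, SpliceClass.CONSTITUTIVE, 5))
        )
        from exon5uc.features import revcomp

        for gene in ds.genes:
            tx = gene.transcripts[0]
            first_cds = tx.cds[0]
            seq = ds.genome[gene.chrom][first_cds.start : first_cds.end]
            codon = seq[:3] if gene.strand == "+" else revcomp(seq)[:3]
            assert codon == "ATG"


class TestJunctionCounts:
    def test_full_inclusion_means_no_skip_reads(self):
        cfg = SimulationConfig(
            seed=3,
            quotas=only(CodingType.TYPE3_CDS, SpliceClass.ASE, 5),
            psi_uniform=(1.0, 1.0),
            tissues={"liver": 0.0},
            samples_per_tissue=3,
        )
        ds = simulate_annotation(cfg)
        samples, _ = simulate_junction_counts(ds)
        for s in samples:
            for ev in ds.truth_events.itertuples():
                assert s.get(tuple(ev.skip_junction)) == 0

    def test_zero_depth_means_zero_counts_and_na_psi(self):
        cfg = SimulationConfig(
            seed=3,
            quotas=only(CodingType.TYPE3_CDS, SpliceClass.ASE, 3),
            depth=0,
            tissues={"liver": 0.0},
            samples_per_tissue=2,
        )
        ds = simulate_annotation(cfg)
        samples, tmap = simulate_junction_counts(ds)
        assert all(sum(s.counts.values()) == 0 for s in samples)
        from exon5uc.splicing import tissue_psi_matrix

        events = generate_se_events(ds.genes)
        m = tissue_psi_matrix(events, samples, tmap)
        assert m.isna().all().all()

    def test_mean_estimated_psi_tracks_truth(self):
        """pi = 0.5 at depth 400, 50 samples: mean estimate within +-0.02."""
        cfg = SimulationConfig(
            seed=8,
            quotas=only(CodingType.TYPE3_CDS, SpliceClass.ASE, 10),
            psi_uniform=(0.5, 0.5),
            depth=400,
            tissues={"t": 0.0},
            samples_per_tissue=50,
        )
        ds = simulate_annotation(cfg)
        samples, _ = simulate_junction_counts(ds)
        from exon5uc.splicing import compute_psi, generate_se_events

        events = generate_se_events(ds.genes)
        vals = [
            compute_psi(ev, s).value for ev in events for s in samples
        ]
        assert np.nanmean(vals) == pytest.approx(0.5, abs=0.02)


class TestCoverage:
    def test_planted_fold_reached_in_upstream_window(self):
        rng = np.random.default_rng(0)
        exons = [
            GenomicInterval("chr1", 5000 * i + 2000, 5000 * i + 2150, "+")
            for i in range(200)
        ]
        track = coverage_for_exons(
            exons, [True] * 200, rng, fold=3.0, width=300, lambda_bg=5.0
        )
        inside, outside = [], []
        for e in exons:
            edges = np.arange(e.start - 500, e.start + 1, 10, dtype=float)
            row = track.binned_mean(e.chrom, edges)
            inside.append(row[20:])  # within 300 nt of the splice site
            outside.append(row[:20])
        assert np.mean(inside) == pytest.approx(15.0, rel=0.05)
        assert np.mean(outside) == pytest.approx(5.0, rel=0.05)

    def test_fold_one_is_indistinguishable(self):
        rng = np.random.default_rng(1)
        exons = [
            GenomicInterval("chr1", 5000 * i + 2000, 5000 * i + 2150, "+")
            for i in range(100)
        ]
        track = coverage_for_exons(exons, [True] * 100, rng, fold=1.0, lambda_bg=5.0)
        means = []
        for e in exons:
            edges = np.arange(e.start - 500, e.start + 1, 10, dtype=float)
            means.append(track.binned_mean(e.chrom, edges))
        assert np.mean(means) == pytest.approx(5.0, rel=0.05)

    def test_minus_strand_enrichment_is_genomically_downstream(self):
        rng = np.random.default_rng(2)
        exon = GenomicInterval("chr1", 2000, 2150, "-")
        track = coverage_for_exons([exon], [True], rng, fold=50.0, lambda_bg=2.0)
        up_edges = np.arange(2150, 2150 + 501, 10, dtype=float)  # after the exon
        down_edges = np.arange(1500, 2001, 10, dtype=float)  # before the exon
        assert track.binned_mean("chr1", up_edges).mean() > 50
        assert track.binned_mean("chr1", down_edges).mean() < 10

    def test_simulate_coverage_covers_event_exons(self, sim_dataset):
        track, frame = simulate_coverage(sim_dataset)
        assert len(frame) == len(sim_dataset.truth_events)
        assert set(frame.chrom).issubset(set(track.chroms))


class TestKnockdown:
    def test_bound_events_shift_up_by_kd_effect(self):
        cfg = SimulationConfig(
            seed=5,
            quotas=only(CodingType.TYPE2_5UC, SpliceClass.ASE, 20),
            psi_uniform=(0.4, 0.5),
            bound_fraction=1.0,
            kd_effect=0.3,
            noise_sigma=0.0,
        )
        ds = simulate_annotation(cfg)
        ctrl, kd, truth = simulate_knockdown(ds)
        assert np.allclose(truth.planted_dpsi, 0.3)
        from exon5uc.splicing import generate_se_events, psi_from_tpm

        for ev in generate_se_events(ds.genes):
            assert psi_from_tpm(ev, kd) - psi_from_tpm(ev, ctrl) == pytest.approx(0.3)

    def test_unbound_events_stay_neutral_without_indirect_effects(self):
        cfg = SimulationConfig(
            seed=5,
            quotas=only(CodingType.TYPE2_5UC, SpliceClass.ASE, 20),
            bound_fraction=0.0,
            kd_down_fraction=0.0,
            noise_sigma=0.05,
        )
        ds = simulate_annotation(cfg)
        _, _, truth = simulate_knockdown(ds)
        assert (truth.planted_dpsi == 0).all()


class TestSpeciesSets:
    def test_zero_loss_keeps_everything(self):
        cfg = SimulationConfig(seed=0, loss_rate=0.0, pool_size=50)
        sets, maps, _ = simulate_species_sets(cfg)
        assert all(len(s) == 50 for s in sets.values())
        from exon5uc.evolution import sharing_distance

        d = sharing_distance(sets, maps)
        assert np.allclose(d, 0.0)

    def test_total_loss_on_one_branch_maximises_distance(self):
        cfg = SimulationConfig(
            seed=0,
            tree="(a:1000,(b:1,c:1):1);",
            loss_rate=0.15,
            pool_size=100,
        )
        sets, maps, _ = simulate_species_sets(cfg)
        assert sets["a"] == set()
        from exon5uc.evolution import sharing_distance

        d = sharing_distance(sets, maps)
        assert d.loc["a", "b"] == 1.0 and d.loc["a", "c"] == 1.0

    def test_determinism(self):
        cfg = SimulationConfig(seed=13)
        s1, _, _ = simulate_species_sets(cfg)
        s2, _, _ = simulate_species_sets(cfg)
        assert s1 == s2

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_sets(SimulationConfig(seed=0, tree="(a:1,b:1);"))
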