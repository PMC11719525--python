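"""Skipped-exon events, PSI formula, tissue aggregation and dPSI groups."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from exon5uc.models import CodingType, SpliceClass
from exon5uc.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_junction_counts,
)
from exon5uc.splicing import (
    JunctionCounts,
    SkippingEvent,
    compute_psi,
    delta_psi_condition,
    generate_se_events,
    moderate_fraction,
    psi_from_tpm,
    read_junction_gct,
    tissue_delta_psi,
    tissue_psi_matrix,
    write_junction_gct,
)

from conftest import iv, make_gene


def simple_event(inclusion=("TI",), exclusion=("TX",)):
    return SkippingEvent(
        event_id="G1;SE:chr1:100-201:300-401:+",
        gene_id="G1",
        skipped_exon=iv(200, 300),
        upstream_junction=("chr1", 100, 200),
        downstream_junction=("chr1", 300, 400),
        skipping_junction=("chr1", 100, 400),
        inclusion_transcripts=tuple(inclusion),
        exclusion_transcripts=tuple(exclusion),
    )


def counts(u, d, s):
    return JunctionCounts(
        sample_id="S",
        counts={
            ("chr1", 100, 200): u,
            ("chr1", 300, 400): d,
            ("chr1", 100, 400): s,
        },
    )


class TestEventGeneration:
    def test_three_exon_gene_with_skipping_isoform(self):
        gene = make_gene(
            [
                ("T1", [(0, 100), (200, 300), (400, 500)], []),
                ("T2", [(0, 100), (400, 500)], []),
            ]
        )
        events = generate_se_events([gene])
        assert len(events) == 1
        ev = events[0]
        assert ev.skipped_exon.coords() == ("chr1", 200, 300, "+")
        assert ev.inclusion_transcripts == ("T1",)
        assert ev.exclusion_transcripts == ("T2",)
        assert ev.event_id == "G1;SE:chr1:100-201:300-401:+"

    def test_no_exclusion_isoform_no_event(self):
        gene = make_gene([("T1", [(0, 100), (200, 300), (400, 500)], [])])
        assert generate_se_events([gene]) == []

    def test_planted_events_recovered_exactly(self, sim_dataset):
        events = generate_se_events(sim_dataset.genes)
        assert {e.event_id for e in events} == set(
            sim_dataset.truth_events.event_id
        )

    def test_matches_brute_force_oracle_on_random_genes(self):
        """Enumerate all flank triples x all isoform junction sets by brute force."""
        rng = np.random.default_rng(12)
        grid = [(100 * i, 100 * i + 50) for i in range(6)]
        for trial in range(40):
            isoforms = []
            for t in range(rng.integers(2, 5)):
                size = int(rng.integers(2, 7))
                idx = sorted(rng.choice(6, size=size, replace=False))
                isoforms.append((f"T{t}", [grid[i] for i in idx], []))
            gene = make_gene(isoforms, gid=f"G{trial}")
            got = {
                (e.upstream_junction, e.downstream_junction, e.skipping_junction)
                for e in generate_se_events([gene])
            }
            junc = {
                tid: {
                    (a[1], b[0])
                    for a, b in zip(ex, ex[1:])
                }
                for tid, ex, _ in isoforms
            }
            expected = set()
            for tid, ex, _ in isoforms:
                for a, b, c in zip(ex, ex[1:], ex[2:]):
                    if any((a[1], c[0]) in js for js in junc.values()):
                        expected.add(
                            (
                                ("chr1", a[1], b[0]),
                                ("chr1", b[1], c[0]),
                                ("chr1", a[1], c[0]),
                            )
                        )
            assert got == expected


class TestPsi:
    @pytest.mark.parametrize(
        "u,d,s,expected",
        [
            (30, 30, 10, 0.75),
            (40, 40, 0, 1.0),
            (0, 0, 60, 0.0),
        ],
    )
    def test_formula(self, u, d, s, expected):
        psi = compute_psi(simple_event(), counts(u, d, s))
        assert psi.value == pytest.approx(expected)

    def test_threshold_is_strict(self):
        """u+d+s = 50 exactly fails the '> 50' rule."""
        assert compute_psi(simple_event(), counts(20, 20, 10)).is_na
        assert not compute_psi(simple_event(), counts(20, 20, 11)).is_na

    def test_scale_invariance(self):
        base = compute_psi(simple_event(), counts(30, 30, 10)).value
        for k in (2, 5, 17):
            assert compute_psi(
                simple_event(), counts(30 * k, 30 * k, 10 * k)
            ).value == pytest.approx(base)

    def test_missing_junctions_count_zero(self):
        psi = compute_psi(
            simple_event(), JunctionCounts(sample_id="S", counts={})
        )
        assert psi.is_na and psi.u == psi.d == psi.s == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            JunctionCounts(sample_id="S", counts={("chr1", 0, 10): -1})


class TestPsiFromTpm:
    def test_simple_ratio(self):
        assert psi_from_tpm(
            simple_event(), {"TI": 8.0, "TX": 2.0}
        ) == pytest.approx(0.8)

    def test_zero_denominator_is_na(self):
        assert math.isnan(psi_from_tpm(simple_event(), {"TI": 0.0, "TX": 0.0}))

    def test_multiple_inclusion_isoforms(self):
        ev = simple_event(inclusion=("I1", "I2", "I3"), exclusion=("X1",))
        tpms = {"I1": 1.0, "I2": 2.0, "I3": 3.0, "X1": 4.0}
        assert psi_from_tpm(ev, tpms) == pytest.approx(0.6)

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            psi_from_tpm(simple_event(), {"TI": -1.0})


class TestTissueAggregation:
    def test_median_over_samples(self):
        ev = simple_event()
        s1 = counts(20, 20, 30)  # PSI 0.4
        s1.sample_id = "a"
        s2 = counts(30, 30, 20)  # PSI 0.6
        s2.sample_id = "b"
        m = tissue_psi_matrix([ev], [s1, s2], {"a": "liver", "b": "liver"})
        assert m.loc[ev.event_id, "liver"] == pytest.approx(0.5)

    def test_all_below_threshold_gives_na(self):
        ev = simple_event()
        s1 = counts(5, 5, 5)
        s1.sample_id = "a"
        m = tissue_psi_matrix([ev], [s1], {"a": "liver"})
        assert m.isna().all().all()

    def test_unknown_sample_in_map_raises(self):
        ev = simple_event()
        s1 = counts(30, 30, 10)
        s1.sample_id = "a"
        with pytest.raises(KeyError, match="ghost"):
            tissue_psi_matrix([ev], [s1], {"a": "liver", "ghost": "liver"})

    def test_binomial_sampling_recovers_true_psi(self):
        """20 samples at depth 200 around PSI 0.7: tissue PSI within +-0.03."""
        quotas = {(ct, sc): 0 for ct in CodingType for sc in SpliceClass}
        quotas[(CodingType.TYPE3_CDS, SpliceClass.ASE)] = 30
        cfg = SimulationConfig(
            seed=5,
            quotas=quotas,
            psi_uniform=(0.7, 0.7),
            tissues={"liver": 0.0},
            samples_per_tissue=20,
            depth=200,
        )
        ds = simulate_annotation(cfg)
        samples, tmap = simulate_junction_counts(ds)
        events = generate_se_events(ds.genes)
        m = tissue_psi_matrix(events, samples, tmap)
        assert (m["liver"] - 0.7).abs().max() < 0.03


class TestTissueDeltaPsi:
    def test_constant_psi_gives_zero_deltas(self):
        m = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.5]}, index=["e1"])
        d = tissue_delta_psi(m)
        assert (d.loc["e1"] == 0).all()

    def test_symmetric_deltas(self):
        m = pd.DataFrame({"a": [0.2], "b": [0.5], "c": [0.8]}, index=["e1"])
        d = tissue_delta_psi(m)
        assert list(d.loc["e1"]) == pytest.approx([-0.3, 0.0, 0.3])

    def test_median_of_deltas_is_zero_for_odd_tissue_count(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        d = tissue_delta_psi(m)
        assert d.median(axis=1).abs().max() == 0

    def test_events_with_few_tissues_excluded(self):
        m = pd.DataFrame(
            {"a": [0.5, 0.5], "b": [np.nan, 0.5], "c": [np.nan, 0.5]},
            index=["sparse", "full"],
        )
        d = tissue_delta_psi(m, min_tissues=3)
        assert list(d.index) == ["full"]

    def test_shifted_tissue_has_largest_median_abs_delta(self, sim_dataset):
        samples, tmap = simulate_junction_counts(sim_dataset)
        events = generate_se_events(sim_dataset.genes)
        m = tissue_psi_matrix(events, samples, tmap)
        d = tissue_delta_psi(m).abs().median()
        assert d.idxmax() == "brain"  # the most-shifted tissue in the defaults


class TestModerateFractionAndGroups:
    def test_fraction_strictly_inside_band(self):
        assert moderate_fraction([0.1, 0.5, 0.9, 1.0]) == pytest.approx(0.25)
        assert moderate_fraction([0.3, 0.75]) == 0.0  # boundaries excluded
        assert math.isnan(moderate_fraction([]))
        assert math.isnan(moderate_fraction([float("nan")]))

    @pytest.mark.parametrize(
        "kd,ctrl,group",
        [
            (0.9, 0.6, "UP"),
            (0.5, 0.5, "NEUTRAL"),
            (0.2, 0.0, "UP"),  # boundary dPSI = 0.2 belongs to UP
            (0.0, 0.2, "DOWN"),  # boundary dPSI = -0.2 belongs to DOWN
            (0.45, 0.5, "NEUTRAL"),
        ],
    )
    def test_dpsi_bands(self, kd, ctrl, group):
        dpsi, label = delta_psi_condition(kd, ctrl)
        assert label == group
        assert dpsi == pytest.approx(kd - ctrl)

    def test_missing_psi_rejected(self):
        with pytest.raises(ValueError):
            delta_psi_condition(float("nan"), 0.5)


class TestGctRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        s1 = counts(30, 30, 10)
        s1.sample_id = "a"
        s2 = counts(1, 2, 3)
        s2.sample_id = "b"
        path = tmp_path / "j.gct"
        write_junction_gct([s1, s2], path)
        back = read_junction_gct(path)
        assert {s.sample_id: s.counts for s in back} == {
            "a": s1.counts,
            "b": s2.counts,
        }
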