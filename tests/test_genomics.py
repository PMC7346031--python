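"""CNV calling thresholds, gene mapping and enrichment tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from glycochol import CnvConfig, CnvSegment, GeneInterval
from glycochol.genomics import (
    GeneEvent,
    call_cnv_events,
    map_events_to_genes,
    mutation_events,
    score_vs_gene_association,
    test_event_enrichment as event_enrichment,
)
from glycochol.io_formats import Mutation
from glycochol.subtyping import MetabolicScore

from .conftest import standardized_matrix


def seg(sample="S1", chrom="chr1", start=0, end=1000, probes=15, mean=0.5, copy=None):
    return CnvSegment(sample, chrom, start, end, probes, mean, copy_status=copy)


# every threshold boundary exercised; expected outcome computed by hand
BOUNDARY_SEGMENTS = [
    (seg(probes=12, mean=0.35, copy=4), "AMP"),    # all amp criteria met
    (seg(probes=9, mean=0.50, copy=5), None),      # probe floor (9 < 10)
    (seg(probes=10, mean=0.50, copy=5), "AMP"),    # probe floor boundary
    (seg(probes=15, mean=0.20, copy=3), None),     # strict > 0.2
    (seg(probes=15, mean=0.21, copy=3), "AMP"),    # just above the mean cut
    (seg(probes=15, mean=0.50, copy=2), None),     # copy 2 < 3 blocks AMP
    (seg(probes=15, mean=0.50, copy=3), "AMP"),    # copy boundary inclusive
    (seg(probes=15, mean=-0.25, copy=1), "DEL"),   # all del criteria met
    (seg(probes=15, mean=-0.20, copy=1), None),    # strict < -0.2
    (seg(probes=15, mean=-0.21, copy=2), None),    # copy 2 > 1 blocks DEL
    (seg(probes=15, mean=-0.35, copy=None), "DEL"),  # no copy status: mean rule
    (seg(probes=15, mean=0.05, copy=None), None),  # neutral segment
]


class TestCnvCaller:
    def test_boundary_segments(self):
        segments = [s for s, _ in BOUNDARY_SEGMENTS]
        called = call_cnv_events(segments, CnvConfig())
        expected = [(s, c) for s, c in BOUNDARY_SEGMENTS if c is not None]
        assert [(c.segment, c.event_class) for c in called] == expected

    def test_idempotent_and_order_invariant(self, rng):
        segments = [s for s, _ in BOUNDARY_SEGMENTS]
        base = call_cnv_events(segments)
        perm = [segments[i] for i in rng.permutation(len(segments))]
        shuffled = call_cnv_events(perm)
        assert {(c.segment, c.event_class) for c in shuffled} == {
            (c.segment, c.event_class) for c in base
        }

    def test_tightening_thresholds_monotone(self, rng):
        segments = [
            seg(
                probes=int(rng.integers(1, 30)),
                mean=float(rng.normal(0, 0.4)),
                copy=int(rng.integers(0, 6)),
            )
            for _ in range(200)
        ]
        loose = len(call_cnv_events(segments, CnvConfig()))
        for cfg in (
            CnvConfig(min_probes=15),
            CnvConfig(amp_mean=0.3, del_mean=-0.3),
            CnvConfig(amp_copy=4, del_copy=0),
        ):
            assert len(call_cnv_events(segments, cfg)) <= loose


class TestGeneMapping:
    GENES = [
        GeneInterval("A", "chr1", 150, 250),
        GeneInterval("B", "chr1", 200, 300),
        GeneInterval("C", "chr2", 0, 100),
    ]

    def test_one_bp_overlap_counts(self):
        called = call_cnv_events([seg(start=100, end=200, mean=0.5, probes=15)])
        events = map_events_to_genes(called, self.GENES)
        assert events == [GeneEvent("A", "S1", "AMP")]

    def test_half_open_abutment_is_no_overlap(self):
        called = call_cnv_events([seg(start=100, end=150, mean=0.5, probes=15)])
        assert map_events_to_genes(called, self.GENES) == []

    def test_segment_spanning_two_genes(self):
        called = call_cnv_events([seg(start=100, end=260, mean=-0.5, probes=15, copy=1)])
        events = map_events_to_genes(called, self.GENES)
        assert {e.gene_id for e in events} == {"A", "B"}
        assert all(e.event_class == "DEL" for e in events)

    def test_duplicate_gene_sample_class_collapsed(self):
        called = call_cnv_events(
            [seg(start=100, end=200, mean=0.5), seg(start=140, end=260, mean=0.4)]
        )
        events = map_events_to_genes(called, self.GENES)
        assert events.count(GeneEvent("A", "S1", "AMP")) == 1

    def test_mutation_events_lifted(self):
        muts = [Mutation("TP53", "S1", "SNV"), Mutation("TP53", "S1", "SNV")]
        assert mutation_events(muts) == [GeneEvent("TP53", "S1", "SNV")]


class TestEnrichment:
    def test_perfect_association_hypergeometric_p(self):
        labels = pd.Series(
            ["A"] * 10 + ["B"] * 10, index=[f"S{i}" for i in range(20)]
        )
        events = [GeneEvent("MYC", f"S{i}", "AMP") for i in range(10)]
        table = event_enrichment(events, labels, include_pooled=False)
        row = table[(table.gene == "MYC") & (table.event_class == "AMP")
                    & (table.subtype == "A")].iloc[0]
        assert row.p_value == pytest.approx(2 / comb(20, 10), abs=1e-15)
        # one gene, one class, two subtypes -> BH over the family
        assert row.p_adjusted <= 0.05

    def test_independent_events_null(self):
        labels = pd.Series(
            ["A"] * 10 + ["B"] * 10, index=[f"S{i}" for i in range(20)]
        )
        events = [GeneEvent("G", f"S{i}", "SNV") for i in range(0, 20, 2)]
        table = event_enrichment(events, labels, include_pooled=False)
        assert (table.dropna(subset=["p_value"]).p_value == 1.0).all()

    def test_gene_without_events_reported_na(self):
        labels = pd.Series(["A", "B"], index=["S0", "S1"])
        events = [GeneEvent("G1", "S0", "AMP")]
        table = event_enrichment(
            events, labels, gene_panel=["G1", "G2"], include_pooled=False
        )
        g2 = table[table.gene == "G2"]
        assert g2.p_value.isna().all()

    def test_unlabeled_sample_rejected(self):
        labels = pd.Series(["A"], index=["S0"])
        with pytest.raises(ValueError, match="unlabeled"):
            event_enrichment([GeneEvent("G", "S9", "AMP")], labels)

    def test_pooled_any_class_present(self):
        labels = pd.Series(["A", "B"], index=["S0", "S1"])
        events = [GeneEvent("G", "S0", "AMP"), GeneEvent("G", "S1", "SNV")]
        table = event_enrichment(events, labels)
        assert "ANY" in set(table.event_class)


class TestScoreAssociation:
    def test_target_equal_to_score_gives_r_one(self, rng):
        n = 30
        chol = rng.normal(size=n)
        samples = [f"S{i}" for i in range(n)]
        scores = [MetabolicScore(s, 0.0, float(c)) for s, c in zip(samples, chol)]
        matrix = standardized_matrix(chol[None, :], genes=["MYC"], samples=samples)
        events = [GeneEvent("MYC", s, "AMP") for s in samples[:10]]
        out = score_vs_gene_association(scores, matrix, events, "MYC")
        assert out["correlation"].statistic == pytest.approx(1.0)

    def test_shifted_carriers_detected_by_rank_sum(self, rng):
        n = 60
        carrier = np.arange(n) < 20
        chol = rng.normal(size=n) + 1.5 * carrier
        samples = [f"S{i}" for i in range(n)]
        scores = [MetabolicScore(s, 0.0, float(c)) for s, c in zip(samples, chol)]
        matrix = standardized_matrix(rng.normal(size=(1, n)), genes=["MYC"], samples=samples)
        events = [GeneEvent("MYC", s, "AMP") for s, f in zip(samples, carrier) if f]
        out = score_vs_gene_association(scores, matrix, events, "MYC")
        assert out["rank_sum"].p_value < 0.01

    def test_small_group_rejected(self, rng):
        samples = [f"S{i}" for i in range(10)]
        scores = [MetabolicScore(s, 0.0, 0.5) for s in samples]
        matrix = standardized_matrix(rng.normal(size=(1, 10)), genes=["MYC"], samples=samples)
        events = [GeneEvent("MYC", "S0", "AMP")]
        with pytest.raises(ValueError, match="fewer than 3"):
            score_vs_gene_association(scores, matrix, events, "MYC")
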