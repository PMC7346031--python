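"""Copy-number event calling, gene mapping and subtype association tests.

A segment is called amplified when it has at least ``min_probes`` support
probes, a segment mean strictly above ``amp_mean`` and — when an integer
copy status is present — a copy status of at least ``amp_copy``; deletion
is symmetric.  Segments without a copy-status column are called on probes
and segment mean alone.  Called segments are mapped to genes by >= 1 bp
overlap in half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CnvConfig
from .io_formats import CnvSegment, GeneInterval, Mutation
from .stats import TestResult, bh_adjust, fisher_exact_2x2, pearson, wilcoxon_rank_sum
from .subtyping import MetabolicScore

__all__ = [
    "GeneEvent",
    "CalledSegment",
    "call_cnv_events",
    "map_events_to_genes",
    "mutation_events",
    "test_event_enrichment",
    "score_vs_gene_association",
]

EVENT_CLASSES = ("AMP", "DEL", "SNV", "INDEL")
#: Pooled convenience class: any of the four primary classes.
ANY_EVENT = "ANY"


@dataclass(frozen=True)
class GeneEvent:
    gene_id: str
    sample_id: str
    event_class: str

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


@dataclass(frozen=True)
class CalledSegment:
    segment: CnvSegment
    event_class: str  # AMP or DEL


def call_cnv_events(
    segments: Sequence[CnvSegment], config: CnvConfig | None = None
) -> list[CalledSegment]:
    """Classify segments as AMP/DEL; uncalled segments are dropped silently."""
    config = config or CnvConfig()
    called: list[CalledSegment] = []
    for seg in segments:
        if seg.n_probes < config.min_probes:
            continue
        copy_ok_amp = seg.copy_status is None or seg.copy_status >= config.amp_copy
        copy_ok_del = seg.copy_status is None or seg.copy_status <= config.del_copy
        if seg.seg_mean > config.amp_mean and copy_ok_amp:
            called.append(CalledSegment(segment=seg, event_class="AMP"))
        elif seg.seg_mean < config.del_mean and copy_ok_del:
            called.append(CalledSegment(segment=seg, event_class="DEL"))
    return called


def map_events_to_genes(
    called: Sequence[CalledSegment], intervals: Sequence[GeneInterval]
) -> list[GeneEvent]:
    """One GeneEvent per (gene, sample, class) with >= 1 bp half-open overlap."""
    by_chrom: dict[str, list[GeneInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    seen: set[tuple[str, str, str]] = set()
    events: list[GeneEvent] = []
    for cs in called:
        seg = cs.segment
        for iv in by_chrom.get(seg.chrom, ()):
            if seg.start < iv.end and iv.start < seg.end:
                key = (iv.gene_id, seg.sample_id, cs.event_class)
                if key not in seen:
                    seen.add(key)
                    events.append(GeneEvent(*key))
    return events


def mutation_events(mutations: Sequence[Mutation]) -> list[GeneEvent]:
    """Lift the mutation table into gene events (duplicates collapsed)."""
    seen: set[tuple[str, str, str]] = set()
    out: list[GeneEvent] = []
    for m in mutations:
        key = (m.gene, m.sample_id, m.mut_class)
        if key not in seen:
            seen.add(key)
            out.append(GeneEvent(*key))
    return out


def test_event_enrichment(
    events: Sequence[GeneEvent],
    labels: Mapping[str, str] | pd.Series,
    gene_panel: Sequence[str] | None = None,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Per-(gene, class, subtype) Fisher tests with joint BH adjustment.

    For each gene and event class, every subtype is contrasted against the
    remaining samples in a 2x2 table (in subtype vs not) x (event vs none),
    tested two-sided.  BH runs jointly over all computed tests.  Genes in
    ``gene_panel`` without any event of a class appear as NA rows.  With
    ``include_pooled`` a synthetic class pooling all event types per gene
    is tested as well.
    """
    labels = pd.Series(labels)
    unlabeled = sorted({e.sample_id for e in events} - set(labels.index))
    if unlabeled:
        raise ValueError(f"events on unlabeled samples: {unlabeled[:5]}")
    samples = list(labels.index)
    subtypes = sorted(labels.unique())
    carriers: dict[tuple[str, str], set[str]] = {}
    for e in events:
        carriers.setdefault((e.gene_id, e.event_class), set()).add(e.sample_id)
        if include_pooled:
            carriers.setdefault((e.gene_id, ANY_EVENT), set()).add(e.sample_id)
    genes = sorted({g for g, _ in carriers})
    if gene_panel is not None:
        genes = sorted(set(genes) | set(gene_panel))
    classes = list(EVENT_CLASSES) + ([ANY_EVENT] if include_pooled else [])
    rows = []
    for gene in genes:
        for cls in classes:
            carrier_set = carriers.get((gene, cls))
            for subtype in subtypes:
                in_sub = labels == subtype
                if carrier_set is None:
                    rows.append(
                        dict(
                            gene=gene, event_class=cls, subtype=subtype,
                            n_event_in=0, n_event_out=0,
                            odds_ratio=np.nan, p_value=np.nan,
                        )
                    )
                    continue
                has_event = labels.index.isin(carrier_set)
                a = int(np.sum(in_sub & has_event))
                b = int(np.sum(in_sub & ~has_event))
                c = int(np.sum(~in_sub & has_event))
                d = int(np.sum(~in_sub & ~has_event))
                res = fisher_exact_2x2([[a, b], [c, d]])
                rows.append(
                    dict(
                        gene=gene, event_class=cls, subtype=subtype,
                        n_event_in=a, n_event_out=c,
                        odds_ratio=res.statistic, p_value=res.p_value,
                    )
                )
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    if tested.any():
        df.loc[tested, "p_adjusted"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    return df


def score_vs_gene_association(
    scores: Sequence[MetabolicScore],
    matrix,
    events: Sequence[GeneEvent],
    target_gene: str,
    event_class: str | None = None,
    score_axis: str = "chol",
) -> dict[str, TestResult]:
    """Contrast a metabolic score by event status of one gene.

    Returns a rank-sum comparison of the score between carriers and
    non-carriers of the target gene's event (optionally restricted to one
    event class) and the Pearson correlation between the score and the
    target gene's expression.
    """
    if target_gene not in matrix.gene_ids:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    if score_axis not in ("gly", "chol"):
        raise ValueError("score_axis must be 'gly' or 'chol'")
    score_by_id = {
        s.sample_id: (s.chol_score if score_axis == "chol" else s.gly_score)
        for s in scores
    }
    carrier_ids = {
        e.sample_id
        for e in events
        if e.gene_id == target_gene
        and (event_class is None or e.event_class == event_class)
    }
    with_event = [v for s, v in score_by_id.items() if s in carrier_ids]
    without = [v for s, v in score_by_id.items() if s not in carrier_ids]
    if min(len(with_event), len(without)) < 3:
        raise ValueError("fewer than 3 samples in a comparison group")
    rs = wilcoxon_rank_sum(with_event, without)
    expr = matrix.values.loc[target_gene]
    common = [s for s in matrix.sample_ids if s in score_by_id]
    corr = pearson(
        [score_by_id[s] for s in common], expr.loc[common].to_numpy(dtype=float)
    )
    return {"rank_sum": rs, "correlation": corr}
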