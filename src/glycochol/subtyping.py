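"""Core-cluster selection, metabolic scoring and quadrant subtyping.

Samples are placed in the (glycolytic, cholesterogenic) score plane, where
each score is the median standardized expression of the corresponding
"core" gene cluster, and assigned one of four subtypes by quadrant:
quiescent (both <= 0), glycolytic (gly > 0, chol <= 0), cholesterogenic
(gly <= 0, chol > 0) and mixed (both > 0).  A gene cluster is "core" when
more than 90% of its annotated members are cholesterogenic, or more than
30% are glycolytic; among several candidates the most homogeneous wins
(ties: larger cluster, then lowest cluster id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import consensus_cluster
from .config import ClusterConfig
from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GeneCluster",
    "MetabolicScore",
    "make_gene_clusters",
    "select_core_clusters",
    "compute_metabolic_scores",
    "assign_subtype",
    "assign_subtypes",
    "subtype_table",
    "cluster_metabolic_genes",
    "run_pan_cancer",
    "PanCancerResult",
]

CHOL_CORE_FRACTION = 0.90
GLY_CORE_FRACTION = 0.30


@dataclass
class GeneCluster:
    """A consensus-derived gene cluster with metabolic composition."""

    cluster_id: int
    member_genes: list[str]
    frac_glycolytic: float
    frac_cholesterogenic: float

    @property
    def homogeneity(self) -> float:
        return max(self.frac_glycolytic, self.frac_cholesterogenic)

    @property
    def is_core_gly(self) -> bool:
        return self.frac_glycolytic > GLY_CORE_FRACTION

    @property
    def is_core_chol(self) -> bool:
        return self.frac_cholesterogenic > CHOL_CORE_FRACTION

    @property
    def size(self) -> int:
        return len(self.member_genes)


@dataclass(frozen=True)
class MetabolicScore:
    sample_id: str
    gly_score: float
    chol_score: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gly_score) and math.isfinite(self.chol_score)):
            raise ValueError(f"sample {self.sample_id}: non-finite metabolic score")


def make_gene_clusters(
    genes: Sequence[str],
    labels: Sequence[int],
    gly_genes: Sequence[str],
    chol_genes: Sequence[str],
) -> list[GeneCluster]:
    """Annotate clustering output with glycolytic/cholesterogenic fractions.

    Fractions are computed over the cluster members annotated in either
    input gene set; a cluster with no annotated member gets fractions 0.
    """
    gly = set(gly_genes)
    chol = set(chol_genes)
    clusters: list[GeneCluster] = []
    labels = np.asarray(labels)
    for cid in sorted(set(labels.tolist())):
        members = [g for g, l in zip(genes, labels) if l == cid]
        annotated = [g for g in members if g in gly or g in chol]
        denom = len(annotated)
        n_gly = sum(1 for g in annotated if g in gly)
        n_chol = sum(1 for g in annotated if g in chol)
        clusters.append(
            GeneCluster(
                cluster_id=int(cid),
                member_genes=members,
                frac_glycolytic=n_gly / denom if denom else 0.0,
                frac_cholesterogenic=n_chol / denom if denom else 0.0,
            )
        )
    return clusters


def _best_candidate(
    candidates: list[GeneCluster], key_fraction
) -> GeneCluster:
    # highest relevant fraction, then larger cluster, then lowest id
    return sorted(
        candidates,
        key=lambda c: (-key_fraction(c), -c.size, c.cluster_id),
    )[0]


def select_core_clusters(
    clusters: Sequence[GeneCluster],
) -> tuple[GeneCluster, GeneCluster]:
    """Pick the core glycolytic and cholesterogenic clusters.

    Raises ``ValueError`` naming the category when no cluster qualifies.
    """
    gly_candidates = [c for c in clusters if c.is_core_gly]
    chol_candidates = [c for c in clusters if c.is_core_chol]
    if not gly_candidates:
        best = max((c.frac_glycolytic for c in clusters), default=0.0)
        raise ValueError(
            f"no core glycolytic cluster (> {GLY_CORE_FRACTION:.0%} members); "
            f"best fraction {best:.3f}"
        )
    if not chol_candidates:
        best = max((c.frac_cholesterogenic for c in clusters), default=0.0)
        raise ValueError(
            f"no core cholesterogenic cluster (> {CHOL_CORE_FRACTION:.0%} members); "
            f"best fraction {best:.3f}"
        )
    core_gly = _best_candidate(gly_candidates, lambda c: c.frac_glycolytic)
    core_chol = _best_candidate(chol_candidates, lambda c: c.frac_cholesterogenic)
    return core_gly, core_chol


def compute_metabolic_scores(
    matrix: ExpressionMatrix,
    core_gly: GeneCluster | Sequence[str],
    core_chol: GeneCluster | Sequence[str],
) -> list[MetabolicScore]:
    """Per-sample median standardized expression of each core gene set.

    At least 50% of each core set must be present in the matrix.  The
    median of an even number of values is the mean of the two middle ones.
    """
    if matrix.scale_tag != "standardized":
        raise ValueError("metabolic scores are defined on the standardized scale")
    gene_index = set(matrix.gene_ids)

    def present(core, name):
        members = core.member_genes if isinstance(core, GeneCluster) else list(core)
        hit = [g for g in members if g in gene_index]
        if len(hit) < 0.5 * len(members):
            raise ValueError(
                f"only {len(hit)}/{len(members)} {name} core genes present in matrix"
            )
        return hit

    gly_genes = present(core_gly, "glycolytic")
    chol_genes = present(core_chol, "cholesterogenic")
    gly_scores = np.median(matrix.values.loc[gly_genes].to_numpy(), axis=0)
    chol_scores = np.median(matrix.values.loc[chol_genes].to_numpy(), axis=0)
    return [
        MetabolicScore(sample_id=s, gly_score=float(g), chol_score=float(c))
        for s, g, c in zip(matrix.sample_ids, gly_scores, chol_scores)
    ]


def assign_subtype(score: MetabolicScore) -> str:
    """Quadrant rule: <= 0 is the low side on both axes."""
    if score.gly_score <= 0 and score.chol_score <= 0:
        return "quiescent"
    if score.gly_score > 0 and score.chol_score <= 0:
        return "glycolytic"
    if score.gly_score <= 0 and score.chol_score > 0:
        return "cholesterogenic"
    return "mixed"


def assign_subtypes(scores: Sequence[MetabolicScore]) -> pd.Series:
    """Subtype label per sample, indexed by sample_id."""
    return pd.Series(
        {s.sample_id: assign_subtype(s) for s in scores}, name="subtype"
    )


def subtype_table(scores: Sequence[MetabolicScore]) -> pd.DataFrame:
    """Long-format table: sample_id, gly_score, chol_score, subtype."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "gly_score": [s.gly_score for s in scores],
            "chol_score": [s.chol_score for s in scores],
            "subtype": [assign_subtype(s) for s in scores],
        }
    ).set_index("sample_id", drop=False)


def cluster_metabolic_genes(
    matrix: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    config: ClusterConfig,
) -> tuple[list[GeneCluster], np.ndarray, list[str]]:
    """Consensus-cluster the glycolytic + cholesterogenic genes of a matrix.

    Returns the annotated clusters, the consensus matrix values and the
    clustered gene list (union members present in the matrix).
    """
    gly = gene_sets.by_category("glycolytic")
    chol = gene_sets.by_category("cholesterogenic")
    union = [g for g in matrix.gene_ids if g in set(gly) | set(chol)]
    if len(union) < config.k:
        raise ValueError("fewer metabolic genes in matrix than clusters requested")
    sub = matrix.values.loc[union].to_numpy(dtype=float)
    cm, labels = consensus_cluster(sub, config, item_ids=union)
    clusters = make_gene_clusters(union, labels, gly, chol)
    return clusters, cm.M, union


@dataclass
class PanCancerResult:
    subtype_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    core_info: dict[str, dict] = field(default_factory=dict)
    omissions: list[tuple[str, str]] = field(default_factory=list)

    def omission_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omissions, columns=["dataset", "reason"])


def run_pan_cancer(
    datasets: Mapping[str, tuple[ExpressionMatrix, GeneSetCollection]],
    config: ClusterConfig,
    min_samples: int = 100,
    min_homogeneity: float = 0.75,
) -> PanCancerResult:
    """Subtype many datasets, omitting those without usable core clusters.

    Each dataset is clustered, core clusters are selected with the usual
    > 90% cholesterogenic / > 30% glycolytic rule, and the dataset is
    omitted (with a reason, never an exception) when a category has no
    qualifying cluster or its selected core has homogeneity below
    ``min_homogeneity`` (the bound is inclusive: exactly 0.75 is retained).
    Datasets below ``min_samples`` are omitted up front.
    """
    result = PanCancerResult()
    for name, (matrix, gene_sets) in datasets.items():
        n = len(matrix.sample_ids)
        if n < min_samples:
            result.omissions.append(
                (name, f"only {n} samples (< {min_samples} screening floor)")
            )
            continue
        try:
            clusters, _, _ = cluster_metabolic_genes(matrix, gene_sets, config)
            core_gly, core_chol = select_core_clusters(clusters)
        except ValueError as exc:
            result.omissions.append((name, str(exc)))
            continue
        bad = [
            (cat, core.homogeneity)
            for cat, core in (("glycolytic", core_gly), ("cholesterogenic", core_chol))
            if core.homogeneity < min_homogeneity
        ]
        if bad:
            cat, h = bad[0]
            result.omissions.append(
                (name, f"{cat} core homogeneity {h:.3f} < {min_homogeneity}")
            )
            continue
        scores = compute_metabolic_scores(matrix, core_gly, core_chol)
        result.subtype_tables[name] = subtype_table(scores)
        result.core_info[name] = {
            "core_gly_genes": core_gly.member_genes,
            "core_chol_genes": core_chol.member_genes,
            "core_gly_homogeneity": core_gly.homogeneity,
            "core_chol_homogeneity": core_chol.homogeneity,
        }
    return result
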