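"""Alignment of metabolic subtypes with published expression classifiers.

A :class:`SignatureScheme` carries per-class direction weights (+1 for
genes up in a class, -1 for genes down).  Samples are consensus-clustered
on the signature genes and each cluster is labeled by the class whose
direction-weighted mean expression is highest in it — a deterministic
stand-in for the manual "semi-automatic" assignment step used with such
classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import consensus_cluster
from .config import ClusterConfig
from .io_formats import ExpressionMatrix, GeneSetCollection
from .stats import TestResult, bh_adjust, fisher_exact_2x2, pearson
from .subtyping import MetabolicScore

__all__ = [
    "SignatureScheme",
    "assign_scheme_labels",
    "crosstab_vs_metabolic",
    "signature_score_correlation",
]


@dataclass
class SignatureScheme:
    """A published classifier: classes plus signed signature genes.

    ``weights`` is a genes x classes frame of direction weights in
    {-1, 0, +1}.
    """

    name: str
    classes: list[str]
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError(f"scheme {self.name!r} needs >= 2 classes")
        if len(self.weights.index) < 1:
            raise ValueError(f"scheme {self.name!r} has no signature genes")
        missing = [c for c in self.classes if c not in self.weights.columns]
        if missing:
            raise ValueError(f"scheme {self.name!r}: no weights for classes {missing}")

    @property
    def signature_genes(self) -> list[str]:
        return list(self.weights.index)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @classmethod
    def from_gene_sets(cls, name: str, collection: GeneSetCollection) -> "SignatureScheme":
        """Build a scheme from GMT sets named ``<CLASS>_UP`` / ``<CLASS>_DOWN``."""
        directions: dict[str, dict[str, int]] = {}
        for set_name, members in collection.sets.items():
            if set_name.endswith("_UP"):
                klass, sign = set_name[: -len("_UP")], 1
            elif set_name.endswith("_DOWN"):
                klass, sign = set_name[: -len("_DOWN")], -1
            else:
                raise ValueError(
                    f"signature set {set_name!r} must end in _UP or _DOWN"
                )
            directions.setdefault(klass, {})
            for g in members:
                directions[klass][g] = sign
        classes = sorted(directions)
        genes = sorted({g for d in directions.values() for g in d})
        weights = pd.DataFrame(0, index=genes, columns=classes, dtype=int)
        for klass, d in directions.items():
            for g, sign in d.items():
                weights.loc[g, klass] = sign
        return cls(name=name, classes=classes, weights=weights)


def assign_scheme_labels(
    matrix: ExpressionMatrix,
    scheme: SignatureScheme,
    config: ClusterConfig | None = None,
) -> pd.Series:
    """Cluster samples on the signature genes and label clusters by class.

    Requires at least 50% of the signature genes in the matrix.  Samples
    are consensus-clustered (items = samples, features = signature genes)
    into ``scheme.n_classes`` clusters; each cluster gets the class whose
    direction-weighted mean standardized expression is highest among its
    samples.  A cluster score tie is broken by class order, with a warning.
    """
    if matrix.scale_tag != "standardized":
        raise ValueError("signature alignment expects the standardized scale")
    present = [g for g in scheme.signature_genes if g in set(matrix.gene_ids)]
    absent = [g for g in scheme.signature_genes if g not in set(matrix.gene_ids)]
    if len(present) < 0.5 * len(scheme.signature_genes):
        raise ValueError(
            f"scheme {scheme.name!r}: only {len(present)}/"
            f"{len(scheme.signature_genes)} signature genes present; "
            f"missing {absent[:10]}"
        )
    config = config or ClusterConfig(k=scheme.n_classes)
    if config.k != scheme.n_classes:
        config = ClusterConfig(
            k=scheme.n_classes,
            reps=config.reps,
            p_item=config.p_item,
            p_feature=config.p_feature,
            seed=config.seed,
        )
    X = matrix.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    _, cluster_labels = consensus_cluster(X, config, item_ids=matrix.sample_ids)
    # per-sample class scores: mean over genes of weight * expression
    W = scheme.weights.loc[present, scheme.classes].to_numpy(dtype=float)
    class_scores = (matrix.values.loc[present].to_numpy(dtype=float).T @ W) / len(
        present
    )
    labels = pd.Series(index=matrix.sample_ids, dtype=object, name=scheme.name)
    for c in np.unique(cluster_labels):
        members = cluster_labels == c
        means = class_scores[members].mean(axis=0)
        best = float(means.max())
        winners = [k for k, m in zip(scheme.classes, means) if m == best]
        if len(winners) > 1:
            warnings.warn(
                f"scheme {scheme.name!r}: cluster {c} class-score tie "
                f"{winners}; taking {winners[0]}"
            )
        labels.iloc[np.flatnonzero(members)] = winners[0]
    return labels


def crosstab_vs_metabolic(
    scheme_labels: pd.Series, metabolic_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate scheme classes against metabolic subtypes.

    Returns the contingency table (scheme classes x metabolic subtypes)
    and a table of pairwise subtype-vs-subtype Fisher tests per scheme
    class, BH-adjusted across all pairs.
    """
    if set(scheme_labels.index) != set(metabolic_labels.index):
        raise ValueError("scheme and metabolic labels cover different samples")
    metabolic_labels = metabolic_labels.loc[scheme_labels.index]
    table = pd.crosstab(scheme_labels, metabolic_labels)
    subtypes = list(table.columns)
    rows = []
    for klass in table.index:
        for i, a in enumerate(subtypes):
            for b in subtypes[i + 1:]:
                in_a = int(table.loc[klass, a])
                in_b = int(table.loc[klass, b])
                tot_a = int(table[a].sum())
                tot_b = int(table[b].sum())
                res = fisher_exact_2x2(
                    [[in_a, tot_a - in_a], [in_b, tot_b - in_b]]
                )
                rows.append(
                    dict(
                        scheme_class=klass,
                        subtype_a=a,
                        subtype_b=b,
                        prop_a=in_a / tot_a if tot_a else np.nan,
                        prop_b=in_b / tot_b if tot_b else np.nan,
                        p_value=res.p_value,
                    )
                )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adjusted"] = bh_adjust(tests["p_value"].to_numpy())
    return table, tests


def signature_score_correlation(
    matrix: ExpressionMatrix,
    scores: list[MetabolicScore],
    signature_genes: list[str],
) -> dict[str, TestResult]:
    """Correlate the median signature expression with both metabolic scores."""
    present = [g for g in signature_genes if g in set(matrix.gene_ids)]
    if len(present) < 3:
        raise ValueError("need at least 3 signature genes present")
    sig = np.median(matrix.values.loc[present].to_numpy(dtype=float), axis=0)
    sig_by_sample = dict(zip(matrix.sample_ids, sig))
    common = [s.sample_id for s in scores if s.sample_id in sig_by_sample]
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping samples")
    by_id = {s.sample_id: s for s in scores}
    x = [sig_by_sample[s] for s in common]
    return {
        "gly": pearson(x, [by_id[s].gly_score for s in common]),
        "chol": pearson(x, [by_id[s].chol_score for s in common]),
    }
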