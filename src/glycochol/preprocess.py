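"""Normalization, transformation, filtering and batch correction.

The expression path is: raw counts -> TPM -> log10(TPM + 1) -> per-cohort
gene-wise z-scores.  The published batch-correction step is described only
loosely in the source analysis; here it is a stated per-cohort gene-wise
standardization (center to mean 0, scale to unit SD), which aligns the
cohorts and gives the downstream "score <= 0 / > 0" quadrant rule a
meaningful zero at the cohort-typical expression level.
"""

from __future__ import annotations

import warnings
from math import log2
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .io_formats import ClinicalRecord, ExpressionMatrix

__all__ = [
    "tpm_normalize",
    "log_transform",
    "filter_by_purity",
    "batch_correct",
    "log2fc_screen",
]

LOG2_PER_LOG10 = log2(10.0)


def tpm_normalize(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per sample, ``TPM_i = (count_i / length_i) / sum_j (count_j / length_j)
    * 1e6``; every column of the result sums to 1e6.
    """
    if counts.scale_tag != "counts":
        raise ValueError(f"expected counts input, got {counts.scale_tag!r}")
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths for {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    lengths = lengths.loc[counts.gene_ids]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.values.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total rate: {list(zero.index)}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, scale_tag="tpm")


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(TPM + 1); monotone, maps 0 to 0."""
    if tpm.scale_tag != "tpm":
        raise ValueError(f"expected TPM input, got {tpm.scale_tag!r}")
    if (tpm.values.to_numpy() < 0).any():
        raise ValueError("negative values in TPM matrix")
    return ExpressionMatrix(values=np.log10(tpm.values + 1.0), scale_tag="log10tpm")


def filter_by_purity(
    matrix: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    config: PreprocessConfig | None = None,
    allow_missing: bool = False,
) -> tuple[ExpressionMatrix, list[ClinicalRecord], list[str]]:
    """Drop samples whose tumor purity is strictly below the threshold.

    Samples exactly at the threshold are retained (the exclusion rule is
    "purity < 30%").  Missing purity raises unless ``allow_missing`` is
    set, in which case the sample is kept with a warning.  Returns the
    filtered matrix, the filtered clinical records (matrix sample order),
    and the excluded sample ids.
    """
    config = config or PreprocessConfig()
    by_id = {r.sample_id: r for r in clinical}
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples missing from clinical table: {missing[:5]}")
    keep: list[str] = []
    excluded: list[str] = []
    for s in matrix.sample_ids:
        purity = by_id[s].purity
        if purity is None:
            if not allow_missing:
                raise ValueError(f"sample {s} has no purity value")
            warnings.warn(f"sample {s} has missing purity; retained")
            keep.append(s)
        elif purity < config.purity_threshold:
            excluded.append(s)
        else:
            keep.append(s)
    return matrix.subset_samples(keep), [by_id[s] for s in keep], excluded


def batch_correct(
    matrix: ExpressionMatrix, cohort_labels: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Per-cohort gene-wise z-scoring (mean 0, unit SD within each cohort).

    Genes with zero variance within a cohort are set to 0 there, with a
    warning.  The pooled per-gene mean of the result is 0 by construction.
    """
    labels = pd.Series(cohort_labels)
    missing = [s for s in matrix.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without cohort label: {missing[:5]}")
    labels = labels.loc[matrix.sample_ids]
    out = matrix.values.astype(float).copy()
    n_constant = 0
    for cohort, cols in labels.groupby(labels).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")
        block = out.loc[:, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        constant = sd <= 0
        n_constant += int(constant.sum())
        sd = sd.where(~constant, 1.0)
        z = block.sub(mu, axis=0).div(sd, axis=0)
        z.loc[constant, :] = 0.0
        out.loc[:, cols] = z
    if n_constant:
        warnings.warn(
            f"{n_constant} gene/cohort blocks had zero variance and were set to 0"
        )
    return ExpressionMatrix(values=out, scale_tag="standardized")


def log2fc_screen(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: PreprocessConfig | None = None,
) -> list[str]:
    """Genes whose between-group mean difference is >= the log2 threshold.

    Group means are compared on the log2 scale; ``log10tpm`` input is
    converted by the factor log2(10).  The threshold is inclusive.
    """
    config = config or PreprocessConfig()
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    if matrix.scale_tag not in ("log10tpm", "standardized"):
        raise ValueError(
            "log2fc_screen expects log-scale input (log10tpm or standardized)"
        )
    factor = LOG2_PER_LOG10 if matrix.scale_tag == "log10tpm" else 1.0
    mean_a = matrix.values.loc[:, ga].mean(axis=1)
    mean_b = matrix.values.loc[:, gb].mean(axis=1)
    diff = (mean_a - mean_b).abs() * factor
    return list(diff.index[diff >= config.log2fc_threshold])
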