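"""Synthetic two-cohort tumor transcriptome generator.

The generator plants exactly the structure the downstream analysis looks
for: four metabolic phenotypes mixed in published-cohort proportions, a
glycolytic and a cholesterogenic co-expressed gene block shifted in the
samples where the pathway is active, two cohorts with additive batch
offsets, subtype-linked exponential survival, subtype-enriched MYC
amplification and TP53 deletion segments, and anchor genes (MPC1/MPC2)
whose expression tracks the glycolytic phenotype.

Co-expression model.  Genes of a block share a latent per-sample pathway
activity.  The subtype shift ``delta`` acts on that activity, and a
residual activity term tops the block's gene-gene covariance up to the
configured ``block_correlation`` whenever the subtype signal alone falls
short of it (variance ``tau^2 = max(0, rho - delta^2 p (1-p))`` with
``p`` the active-sample fraction).  With ``delta = 0`` the marginal
within-block correlation is exactly ``rho``; with strong shifts the
subtype structure itself carries the co-expression, as it does in the
data the generator emulates.  Expression is formed on the log10 scale and
exponentiated to pseudo-counts so that the full TPM -> log -> z-score
path can run on the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SimConfig, SUBTYPES
from .io_formats import (
    ClinicalRecord,
    CnvSegment,
    ExpressionMatrix,
    GeneInterval,
    GeneSetCollection,
    Mutation,
    write_bed,
    write_clinical,
    write_expression,
    write_gmt,
    write_mutations,
    write_seg,
)

__all__ = ["SyntheticCohort", "generate_cohort", "write_cohort"]

SPECIAL_GENES = ("MPC1", "MPC2", "MYC", "TP53")


@dataclass
class SyntheticCohort:
    """A fully aligned synthetic dataset with planted ground truth."""

    expression: ExpressionMatrix  # pseudo-counts
    clinical: list[ClinicalRecord]
    segments: list[CnvSegment]
    mutations: list[Mutation]
    gene_sets: GeneSetCollection
    gene_intervals: list[GeneInterval]
    truth_labels: dict[str, str]
    myc_amplified: dict[str, bool]
    tp53_deleted: dict[str, bool]

    def __post_init__(self) -> None:
        samples = self.expression.sample_ids
        if [r.sample_id for r in self.clinical] != samples:
            raise ValueError("clinical records not aligned with expression samples")
        if sorted(self.truth_labels) != sorted(samples):
            raise ValueError("truth_labels must cover exactly the samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {iv.gene_id: iv.length for iv in self.gene_intervals}


def _block(
    rng: np.random.Generator,
    n_genes: int,
    active: np.ndarray,
    p_active: float,
    delta: float,
    rho: float,
) -> np.ndarray:
    """One co-expressed gene block (genes x samples, unit-variance noise)."""
    n = active.size
    tau2 = max(0.0, rho - delta**2 * p_active * (1.0 - p_active))
    tau2 = min(tau2, 0.999)
    activity = delta * active.astype(float) + np.sqrt(tau2) * rng.standard_normal(n)
    noise = np.sqrt(1.0 - tau2) * rng.standard_normal((n_genes, n))
    return activity[None, :] + noise


def _censoring_horizon(rates: np.ndarray, props: np.ndarray, target: float) -> float:
    """Uniform-censoring horizon c with P(C < T) = target for the mixture."""

    def censored_frac(c: float) -> float:
        return float(np.sum(props * (1.0 - np.exp(-rates * c)) / (rates * c)))

    lo, hi = 1e-6, 1e7
    return brentq(lambda c: censored_frac(c) - target, lo, hi, xtol=1e-8)


def _gene_catalog(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], list[str], list[GeneInterval]]:
    """Gene names and a synthetic genome layout (0-based half-open BED)."""
    gly = [f"GLY{i + 1:03d}" for i in range(config.n_gly_genes)]
    chol = [f"CHOL{i + 1:03d}" for i in range(config.n_chol_genes)]
    n_bg_extra = config.n_background_genes - len(SPECIAL_GENES)
    background = list(SPECIAL_GENES) + [f"BG{i + 1:04d}" for i in range(n_bg_extra)]
    genes = gly + chol + background
    intervals = []
    chroms = [f"chr{i}" for i in range(1, 11)]
    per_chrom = int(np.ceil(len(genes) / len(chroms)))
    lengths = rng.integers(1000, 10001, size=len(genes))
    pos = 0
    for i, g in enumerate(genes):
        chrom = chroms[i // per_chrom]
        if i % per_chrom == 0:
            pos = 10_000
        start = pos
        end = start + int(lengths[i])
        intervals.append(GeneInterval(gene_id=g, chrom=chrom, start=start, end=end))
        pos = end + 5_000
    return gly, chol, background, intervals


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort; identical config => identical output.

    One RNG stream per component (genome layout, expression, survival,
    copy number, mutations/clinical), all derived from the master seed, so
    toggling one component leaves the others unchanged.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_genome = np.random.default_rng(streams[0])
    rng_expr = np.random.default_rng(streams[1])
    rng_surv = np.random.default_rng(streams[2])
    rng_cnv = np.random.default_rng(streams[3])
    rng_clin = np.random.default_rng(streams[4])

    n = config.n_samples
    props = np.asarray(config.subtype_proportions, dtype=float)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    label_idx = rng_clin.choice(4, size=n, p=props)
    labels = np.asarray(SUBTYPES)[label_idx]
    gly_active = np.isin(labels, ("glycolytic", "mixed"))
    chol_active = np.isin(labels, ("cholesterogenic", "mixed"))

    gly_genes, chol_genes, bg_genes, intervals = _gene_catalog(config, rng_genome)
    iv_by_gene = {iv.gene_id: iv for iv in intervals}

    # copy-number flags first: the cis effects feed into expression
    p_gly = props[2] + props[3]
    p_chol = props[1] + props[3]
    myc_probs = np.array(
        [config.cnv_enrichment["MYC_AMP"][l] for l in labels]
    )
    tp53_probs = np.array(
        [config.cnv_enrichment["TP53_DEL"][l] for l in labels]
    )
    myc_amp = rng_cnv.random(n) < myc_probs
    tp53_del = rng_cnv.random(n) < tp53_probs

    # expression on the log10 scale
    delta = config.effect_size_delta
    rho = config.block_correlation
    sd = config.log_noise_sd
    core = np.vstack(
        [
            _block(rng_expr, config.n_gly_genes, gly_active, p_gly, delta, rho),
            _block(rng_expr, config.n_chol_genes, chol_active, p_chol, delta, rho),
            rng_expr.standard_normal((config.n_background_genes, n)),
        ]
    )
    genes = gly_genes + chol_genes + bg_genes
    idx = {g: i for i, g in enumerate(genes)}
    core[idx["MPC1"]] += config.mpc_effect * (labels == "glycolytic")
    core[idx["MPC2"]] -= config.mpc_effect * (labels == "glycolytic")
    core[idx["MPC2"]] += 0.5 * (labels == "cholesterogenic")
    core[idx["MYC"]] += 1.0 * myc_amp
    core[idx["TP53"]] -= 1.0 * tp53_del

    # batch structure: a scalar shift per cohort plus gene-specific offsets
    # (a uniform per-sample shift cancels under TPM; the gene-specific part
    # is the batch effect the correction stage has to remove)
    cohort_names = sorted(config.cohort_offsets)
    cohort_of = rng_clin.choice(len(cohort_names), size=n)
    offsets = np.array([config.cohort_offsets[cohort_names[c]] for c in cohort_of])
    gene_batch = config.cohort_gene_sd * rng_expr.standard_normal(
        (len(genes), len(cohort_names))
    )
    gene_batch[:, 0] = 0.0  # first cohort is the reference
    log10_expr = (
        config.base_log10_tpm
        + sd * (core + gene_batch[:, cohort_of])
        + offsets[None, :]
    )
    counts = np.power(10.0, log10_expr)

    expression = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        scale_tag="counts",
    )

    # survival: exponential hazards with uniform independent censoring
    base_rate = np.log(2.0) / config.baseline_median_survival
    hr = np.array([config.hazard_ratios[l] for l in labels])
    rates = base_rate * hr
    t_event = rng_surv.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        mix_rates = base_rate * np.array(
            [config.hazard_ratios[s] for s in SUBTYPES]
        )
        horizon = _censoring_horizon(mix_rates, props, config.censoring_rate)
        c_time = rng_surv.uniform(0.0, horizon, size=n)
        event = (t_event <= c_time).astype(int)
        os_months = np.minimum(t_event, c_time)
    else:
        event = np.ones(n, dtype=int)
        os_months = t_event

    purity = rng_clin.beta(*config.purity_params, size=n)
    metastatic = (rng_clin.random(n) < config.metastatic_rate).astype(int)
    clinical = [
        ClinicalRecord(
            sample_id=s,
            os_months=float(os_months[i]),
            event=int(event[i]),
            cohort=cohort_names[cohort_of[i]],
            purity=float(purity[i]),
            metastatic=int(metastatic[i]),
        )
        for i, s in enumerate(samples)
    ]

    # copy-number segments
    segments: list[CnvSegment] = []
    myc_iv = iv_by_gene["MYC"]
    tp53_iv = iv_by_gene["TP53"]
    for i, s in enumerate(samples):
        if myc_amp[i]:
            segments.append(
                CnvSegment(
                    sample_id=s, chrom=myc_iv.chrom,
                    start=max(0, myc_iv.start - 2000), end=myc_iv.end + 2000,
                    n_probes=int(rng_cnv.integers(20, 80)),
                    seg_mean=float(rng_cnv.normal(0.8, 0.1)),
                    copy_status=int(rng_cnv.integers(3, 6)),
                )
            )
        if tp53_del[i]:
            segments.append(
                CnvSegment(
                    sample_id=s, chrom=tp53_iv.chrom,
                    start=max(0, tp53_iv.start - 2000), end=tp53_iv.end + 2000,
                    n_probes=int(rng_cnv.integers(20, 80)),
                    seg_mean=float(-rng_cnv.normal(0.8, 0.1)),
                    copy_status=int(rng_cnv.integers(0, 2)),
                )
            )
        # copy-neutral background segments exercising the caller's filters
        for _ in range(rng_cnv.poisson(1.0)):
            iv = intervals[int(rng_cnv.integers(0, len(intervals)))]
            segments.append(
                CnvSegment(
                    sample_id=s, chrom=iv.chrom,
                    start=iv.start, end=iv.end + int(rng_cnv.integers(1, 20000)),
                    n_probes=int(rng_cnv.integers(3, 40)),
                    seg_mean=float(rng_cnv.normal(0.0, 0.12)),
                    copy_status=2,
                )
            )

    # small variants, independent of subtype
    mutation_rates = {
        ("TP53", "SNV"): 0.25,
        ("CTNNB1", "SNV"): 0.25,
        ("AXIN1", "SNV"): 0.08,
        ("ARID1A", "INDEL"): 0.06,
    }
    mutations: list[Mutation] = []
    for (gene, cls), rate in mutation_rates.items():
        hit = rng_clin.random(n) < rate
        for i in np.flatnonzero(hit):
            mutations.append(Mutation(gene=gene, sample_id=samples[i], mut_class=cls))

    gene_sets = GeneSetCollection(
        sets={"GLYCOLYSIS": list(gly_genes), "CHOLESTEROL_BIOSYNTHESIS": list(chol_genes)},
        categories={
            "GLYCOLYSIS": "glycolytic",
            "CHOLESTEROL_BIOSYNTHESIS": "cholesterogenic",
        },
    )
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        segments=segments,
        mutations=mutations,
        gene_sets=gene_sets,
        gene_intervals=intervals,
        truth_labels=dict(zip(samples, labels.tolist())),
        myc_amplified=dict(zip(samples, myc_amp.tolist())),
        tp53_deleted=dict(zip(samples, tp53_del.tolist())),
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write every component in its external format; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "segments": directory / "segments.seg",
        "gene_sets": directory / "gene_sets.gmt",
        "gene_intervals": directory / "genes.bed",
        "mutations": directory / "mutations.tsv",
        "truth_labels": directory / "truth_labels.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_seg(cohort.segments, paths["segments"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_bed(cohort.gene_intervals, paths["gene_intervals"])
    write_mutations(cohort.mutations, paths["mutations"])
    with open(paths["truth_labels"], "w") as fh:
        fh.write("sample_id\tsubtype\n")
        for s in cohort.sample_ids:
            fh.write(f"{s}\t{cohort.truth_labels[s]}\n")
    return paths
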