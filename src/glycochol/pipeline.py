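"""End-to-end orchestration: files in, subtype/genomics/survival tables out.

Stage order: read -> TPM -> log10 -> purity filter -> batch correct ->
consensus cluster -> core-cluster selection -> metabolic scores ->
quadrant assignment -> genomic-event association -> survival contrasts ->
(optional) signature alignment.  Every output table is stamped with the
configuration hash and seed; re-running the same configuration on the
same inputs reproduces all outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomics, preprocess, survival as surv
from .alignment import SignatureScheme, assign_scheme_labels, crosstab_vs_metabolic
from .config import PipelineConfig, SUBTYPES
from .io_formats import (
    ExpressionMatrix,
    clinical_to_frame,
    read_bed,
    read_clinical,
    read_expression,
    read_gmt,
    read_mutations,
    read_seg,
)
from .stats import mpc_correlation_screen
from .subtyping import (
    cluster_metabolic_genes,
    compute_metabolic_scores,
    select_core_clusters,
    subtype_table,
)

logger = logging.getLogger("glycochol")

__all__ = ["PipelineResult", "run_pipeline", "config_hash", "preprocess_cohort"]


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    subtypes: pd.DataFrame
    scores: list
    core_gly_genes: list[str]
    core_chol_genes: list[str]
    consensus: np.ndarray
    clustered_genes: list[str]
    clinical: pd.DataFrame
    enrichment: pd.DataFrame | None = None
    associations: dict = field(default_factory=dict)
    survival_tests: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)
    screen: list = field(default_factory=list)
    excluded_low_purity: list[str] = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def preprocess_cohort(
    counts: ExpressionMatrix,
    clinical_records,
    gene_lengths,
    config: PipelineConfig,
):
    """Counts -> standardized matrix (TPM, log10, purity filter, batch z-score)."""
    tpm = preprocess.tpm_normalize(counts, gene_lengths)
    logged = preprocess.log_transform(tpm)
    filtered, kept_clinical, excluded = preprocess.filter_by_purity(
        logged, clinical_records, config.preprocess
    )
    if config.preprocess.batch_method == "per_cohort_zscore":
        cohorts = {r.sample_id: r.cohort for r in kept_clinical}
        standardized = preprocess.batch_correct(filtered, cohorts)
    else:
        vals = filtered.values
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1).replace(0.0, 1.0)
        standardized = ExpressionMatrix(
            vals.sub(mu, axis=0).div(sd, axis=0), scale_tag="standardized"
        )
    return standardized, kept_clinical, excluded


def run_pipeline(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
    signature_gmt: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a directory of input files.

    Expects the file set written by :func:`glycochol.synthetic.write_cohort`
    (``expression.tsv``, ``clinical.tsv``, ``gene_sets.gmt``, ``genes.bed``,
    optional ``segments.seg`` and ``mutations.tsv``).  When ``output_dir``
    is given, all result tables are written there as TSV plus a JSON run
    summary.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    chash = config_hash(config)

    @_stage("read")
    def read_inputs():
        counts = read_expression(input_dir / "expression.tsv", scale_tag="counts")
        clinical = read_clinical(
            input_dir / "clinical.tsv", time_unit=config.time_unit
        )
        gene_sets = read_gmt(input_dir / "gene_sets.gmt")
        intervals = read_bed(input_dir / "genes.bed")
        seg_path = input_dir / "segments.seg"
        segments = read_seg(seg_path) if seg_path.exists() else []
        mut_path = input_dir / "mutations.tsv"
        mutations = read_mutations(mut_path) if mut_path.exists() else []
        return counts, clinical, gene_sets, intervals, segments, mutations

    counts, clinical, gene_sets, intervals, segments, mutations = read_inputs()
    lengths = {iv.gene_id: iv.length for iv in intervals}

    @_stage("preprocess")
    def do_preprocess():
        return preprocess_cohort(counts, clinical, lengths, config)

    standardized, kept_clinical, excluded = do_preprocess()

    @_stage("cluster")
    def do_cluster():
        return cluster_metabolic_genes(standardized, gene_sets, config.cluster)

    clusters, consensus, clustered_genes = do_cluster()

    @_stage("core_select")
    def do_core():
        return select_core_clusters(clusters)

    core_gly, core_chol = do_core()

    @_stage("score_assign")
    def do_scores():
        scores = compute_metabolic_scores(standardized, core_gly, core_chol)
        return scores, subtype_table(scores)

    scores, subtypes = do_scores()
    labels = subtypes["subtype"]

    result = PipelineResult(
        subtypes=subtypes,
        scores=scores,
        core_gly_genes=core_gly.member_genes,
        core_chol_genes=core_chol.member_genes,
        consensus=consensus,
        clustered_genes=clustered_genes,
        clinical=clinical_to_frame(kept_clinical),
        excluded_low_purity=excluded,
        config_hash=chash,
        seed=config.seed,
    )

    if segments:

        @_stage("genomics")
        def do_genomics():
            called = genomics.call_cnv_events(segments, config.cnv)
            events = genomics.map_events_to_genes(called, intervals)
            events += genomics.mutation_events(mutations)
            events = [e for e in events if e.sample_id in set(labels.index)]
            enrichment = genomics.test_event_enrichment(events, labels)
            associations = {}
            for gene, cls in (("MYC", "AMP"), ("TP53", "DEL")):
                if gene in standardized.gene_ids:
                    try:
                        associations[f"{gene}_{cls}"] = (
                            genomics.score_vs_gene_association(
                                scores, standardized, events, gene, event_class=cls
                            )
                        )
                    except ValueError:
                        pass
            return enrichment, associations

        result.enrichment, result.associations = do_genomics()

    @_stage("survival")
    def do_survival():
        records = surv.filter_min_survival(
            kept_clinical, config.min_survival_months
        )
        frame = clinical_to_frame(records)
        frame = frame.join(labels, how="inner")
        tests = {}
        if frame["subtype"].nunique() >= 2 and frame["event"].sum() >= 1:
            tests["all_subtypes"] = surv.logrank_test(
                frame["os_months"], frame["event"], frame["subtype"]
            )
        pair = frame[frame["subtype"].isin(["cholesterogenic", "glycolytic"])]
        if pair["subtype"].nunique() == 2 and pair["event"].sum() >= 1:
            tests["chol_vs_gly"] = surv.logrank_test(
                pair["os_months"], pair["event"], pair["subtype"]
            )
            for flag, key in ((1, "chol_vs_gly_metastatic"), (0, "chol_vs_gly_non_metastatic")):
                sub = pair[pair["metastatic"] == flag]
                if sub["subtype"].nunique() == 2 and sub["event"].sum() >= 1:
                    tests[key] = surv.logrank_test(
                        sub["os_months"], sub["event"], sub["subtype"]
                    )
        curves = {
            label: surv.km_estimate(grp["os_months"], grp["event"])
            for label, grp in frame.groupby("subtype")
        }
        return tests, curves

    result.survival_tests, _curves = do_survival()

    if "MPC1" in standardized.gene_ids and "MPC2" in standardized.gene_ids:

        @_stage("mpc_screen")
        def do_screen():
            return mpc_correlation_screen(
                standardized, "MPC1", "MPC2", alpha=config.alpha_screen
            )

        result.screen = do_screen()

    if signature_gmt is not None:

        @_stage("alignment")
        def do_alignment():
            sig_sets = read_gmt(signature_gmt)
            scheme = SignatureScheme.from_gene_sets("signature", sig_sets)
            sch_labels = assign_scheme_labels(standardized, scheme, config.cluster)
            table, tests = crosstab_vs_metabolic(sch_labels, labels)
            return {"labels": sch_labels, "table": table, "tests": tests}

        result.alignment = do_alignment()

    if output_dir is not None:
        _write_outputs(result, Path(output_dir), config)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={result.config_hash} seed={result.seed}\n"

    def dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index, float_format="%.10g")

    dump(result.subtypes, "subtypes.tsv")
    if result.enrichment is not None:
        dump(result.enrichment, "enrichment.tsv")
    if len(result.screen):
        dump(
            pd.DataFrame([vars(r) for r in result.screen]),
            "mpc_screen.tsv",
        )
    counts = result.subtypes["subtype"].value_counts().reindex(SUBTYPES).fillna(0)
    summary = {
        "config_hash": result.config_hash,
        "seed": result.seed,
        "n_samples": int(len(result.subtypes)),
        "n_excluded_low_purity": len(result.excluded_low_purity),
        "subtype_counts": {k: int(v) for k, v in counts.items()},
        "survival_p": {
            k: t.p_value for k, t in result.survival_tests.items()
        },
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
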