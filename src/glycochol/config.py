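"""Configuration objects for every pipeline stage, loadable from YAML.

All thresholds default to the published analysis settings: purity
exclusion below 30%, log2 fold-change screen at 1, consensus clustering
with k=5, 100 resampling repetitions at 80% item sampling, CNV calling at
10 probes and |seg.mean| 0.2 with copy-status cutoffs 3/1, and two-sided
alpha 0.05 (0.01 for the correlation screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PreprocessConfig",
    "ClusterConfig",
    "CnvConfig",
    "SimConfig",
    "PipelineConfig",
    "load_config",
    "DEFAULT_SUBTYPE_PROPORTIONS",
    "SUBTYPES",
]

#: Subtype order used everywhere: quadrants of the (glycolytic, cholesterogenic)
#: score plane.
SUBTYPES = ("quiescent", "cholesterogenic", "glycolytic", "mixed")

#: Cohort mixing proportions matching the published subgroup sizes
#: 332/164/65/49 of 610 (quiescent, cholesterogenic, glycolytic, mixed).
DEFAULT_SUBTYPE_PROPORTIONS = (332 / 610, 164 / 610, 65 / 610, 49 / 610)


@dataclass
class PreprocessConfig:
    purity_threshold: float = 0.30
    log2fc_threshold: float = 1.0
    batch_method: str = "per_cohort_zscore"  # or "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity_threshold <= 1.0):
            raise ValueError("purity_threshold must lie in [0, 1]")
        if self.log2fc_threshold < 0:
            raise ValueError("log2fc_threshold must be >= 0")
        if self.batch_method not in ("per_cohort_zscore", "none"):
            raise ValueError(f"unknown batch_method {self.batch_method!r}")


@dataclass
class ClusterConfig:
    k: int = 5
    reps: int = 100
    p_item: float = 0.8
    p_feature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in ("p_item", "p_feature"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class CnvConfig:
    min_probes: int = 10
    amp_mean: float = 0.2
    del_mean: float = -0.2
    amp_copy: int = 3
    del_copy: int = 1

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not (self.amp_mean > 0 > self.del_mean):
            raise ValueError("need amp_mean > 0 > del_mean")


@dataclass
class SimConfig:
    """Parameters of the synthetic two-cohort tumor transcriptome generator.

    ``effect_size_delta`` is the standardized mean shift (in units of the
    per-gene noise SD on the log10 scale) applied to a metabolic gene block
    in the samples where that pathway is active; ``block_correlation`` is
    the target marginal within-block gene-gene correlation.
    """

    n_samples: int = 600
    n_gly_genes: int = 29
    n_chol_genes: int = 72
    n_background_genes: int = 5000
    subtype_proportions: tuple[float, float, float, float] = DEFAULT_SUBTYPE_PROPORTIONS
    effect_size_delta: float = 2.0
    block_correlation: float = 0.5
    cohort_offsets: dict[str, float] = field(
        default_factory=lambda: {"cohortA": 0.0, "cohortB": 0.8}
    )
    cohort_gene_sd: float = 0.3
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "quiescent": 1.5,
            "cholesterogenic": 2.0,
            "glycolytic": 1.0,
            "mixed": 1.6,
        }
    )
    baseline_median_survival: float = 30.0  # months, glycolytic reference arm
    censoring_rate: float = 0.3
    purity_params: tuple[float, float] = (4.0, 2.0)  # Beta(a, b)
    cnv_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "MYC_AMP": {
                "quiescent": 0.12,
                "cholesterogenic": 0.45,
                "glycolytic": 0.12,
                "mixed": 0.30,
            },
            "TP53_DEL": {
                "quiescent": 0.15,
                "cholesterogenic": 0.45,
                "glycolytic": 0.15,
                "mixed": 0.30,
            },
        }
    )
    mpc_effect: float = 1.5
    metastatic_rate: float = 0.3
    base_log10_tpm: float = 2.0
    log_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_gly_genes", "n_chol_genes", "n_background_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != 4 or np.any(props < 0):
            raise ValueError("subtype_proportions must be 4 non-negative entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1 within 1e-9")
        if self.effect_size_delta < 0:
            raise ValueError("effect_size_delta must be >= 0")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in [0, 1)")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValueError("hazard_ratios must all be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.n_background_genes < 4:
            raise ValueError(
                "n_background_genes must be >= 4 (MPC1/MPC2/MYC/TP53 are "
                "placed in the background block)"
            )
        if len(self.cohort_offsets) < 1:
            raise ValueError("need at least one cohort")


@dataclass
class PipelineConfig:
    """Aggregated configuration for an end-to-end run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    alpha_enrichment: float = 0.05
    alpha_screen: float = 0.01
    min_survival_months: float = 1.0
    pan_cancer_min_samples: int = 100
    pan_cancer_min_homogeneity: float = 0.75
    time_unit: str = "months"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict | None):
    return cls(**(data or {}))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Top-level keys ``preprocess``, ``cluster``, ``cnv`` and ``sim`` hold the
    stage sub-configurations; remaining keys map to the flat fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    if sim_raw and "subtype_proportions" in sim_raw:
        sim_raw["subtype_proportions"] = tuple(sim_raw["subtype_proportions"])
    if sim_raw and "purity_params" in sim_raw:
        sim_raw["purity_params"] = tuple(sim_raw["purity_params"])
    cfg = PipelineConfig(
        preprocess=_build(PreprocessConfig, raw.pop("preprocess", None)),
        cluster=_build(ClusterConfig, raw.pop("cluster", None)),
        cnv=_build(CnvConfig, raw.pop("cnv", None)),
        sim=_build(SimConfig, sim_raw),
        **raw,
    )
    return cfg
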