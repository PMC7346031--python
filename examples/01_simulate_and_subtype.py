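"""Simulate a cohort and classify every sample into a metabolic subtype.

Builds a 600-sample synthetic cohort with four planted metabolic
phenotypes, runs the full pipeline (TPM -> log10 -> purity filter ->
per-cohort z-score -> gene consensus clustering -> core-cluster medians
-> quadrant rule) and compares the assigned subtypes with the planted
truth.
"""

import tempfile
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from glycochol import PipelineConfig, SimConfig, generate_cohort, run_pipeline, write_cohort

cohort = generate_cohort(SimConfig(seed=0))

cfg = PipelineConfig()
cfg.cluster.k = 2  # the generator plants exactly two co-expression modules
cfg.cluster.seed = 0

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp) / "cohort"
    write_cohort(cohort, d)
    result = run_pipeline(d, cfg)

truth = pd.Series({s: cohort.truth_labels[s] for s in result.subtypes.index}, name="truth")
pred = result.subtypes["subtype"]

print("samples analysed:", len(pred),
      f"(excluded {len(result.excluded_low_purity)} with purity < 30%)")
print("\nassigned subtype counts:")
print(pred.value_counts().to_string())
print("\ntruth vs assigned:")
print(pd.crosstab(truth, pred).to_string())
print("\nadjusted Rand index vs planted truth:",
      round(adjusted_rand_score(truth, pred), 3))
# An ARI near 1 means the quadrant rule on core-cluster median scores
# recovered the planted phenotypes almost perfectly; the subtype counts
# mirror the planted mixing proportions (54/27/11/8%).
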