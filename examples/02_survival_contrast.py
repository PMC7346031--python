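"""Kaplan-Meier curves and log-rank contrasts between metabolic subtypes.

The synthetic cohort plants subtype-linked exponential hazards with the
cholesterogenic subtype at hazard ratio 2.0 relative to the glycolytic
subtype, so the cholesterogenic arm should show clearly worse survival.
"""

from glycochol import SimConfig, filter_min_survival, generate_cohort, km_estimate, logrank_test
from glycochol.io_formats import clinical_to_frame

cohort = generate_cohort(SimConfig(seed=1))
records = filter_min_survival(cohort.clinical)  # drop survival < 1 month
frame = clinical_to_frame(records)
frame["subtype"] = [cohort.truth_labels[s] for s in frame.index]

for subtype, grp in frame.groupby("subtype"):
    curve = km_estimate(grp["os_months"], grp["event"])
    print(f"{subtype:16s} n={len(grp):3d}  S(24 months)={curve.survival_at(24):.3f}")

res = logrank_test(frame["os_months"], frame["event"], frame["subtype"])
print(f"\n4-group log-rank: chi2={res.statistic:.2f} (3 df), p={res.p_value:.2e}")

pair = frame[frame["subtype"].isin(["cholesterogenic", "glycolytic"])]
res = logrank_test(pair["os_months"], pair["event"], pair["subtype"])
print(f"cholesterogenic vs glycolytic: chi2={res.statistic:.2f}, p={res.p_value:.2e}")
# The pairwise p-value is small because the planted hazard ratio is 2:
# cholesterogenic tumors die roughly twice as fast as glycolytic ones.
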