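# glycochol

Metabolic subtyping of tumor transcriptomes from the co-expression of
glycolysis and cholesterol-biosynthesis genes.

Tumors reprogram their energy metabolism, and in hepatocellular carcinoma
(and several other cancer types) the expression of the glycolytic and the
cholesterogenic pathway stratifies patients into four groups with
different prognoses. `glycochol` implements that analysis as a tested,
reusable pipeline for anyone who has a bulk expression matrix, segmented
copy-number calls and a clinical table — plus a synthetic-cohort generator
that plants the full structure (subtypes, co-expression blocks, batch
effects, survival hazards, copy-number events) so every stage can be
validated without downloading any cohort.

## The method

1. **Normalize**: raw counts → TPM → `log10(TPM + 1)`; samples with tumor
   purity < 30% are excluded; each gene is z-scored within its cohort
   (batch correction), so 0 is the cohort-typical expression level.
2. **Cluster the metabolic genes**: resampling consensus clustering
   (Ward.D2 on Euclidean distances, 100 repetitions at 80% gene
   subsampling, implemented from first principles). The consensus value
   `M[i, j]` is the fraction of co-sampled repetitions in which genes *i*
   and *j* co-clustered.
3. **Select core clusters**: a cluster is a *core* cholesterogenic
   (glycolytic) cluster when > 90% (> 30%) of its annotated members belong
   to that gene set; among candidates the most homogeneous wins.
4. **Score and assign**: per sample, the glycolytic and cholesterogenic
   scores are the median standardized expression of the two core
   clusters, and the quadrant rule assigns

   | gly ≤ 0, chol ≤ 0 | gly > 0, chol ≤ 0 | gly ≤ 0, chol > 0 | gly > 0, chol > 0 |
   |---|---|---|---|
   | quiescent | glycolytic | cholesterogenic | mixed |

5. **Associate**: CNV events (≥ 10 probes, |seg.mean| > 0.2, copy status
   ≥ 3 / ≤ 1) mapped to genes and Fisher/BH-tested per subtype;
   Kaplan-Meier / log-rank survival contrasts; a transcriptome-wide
   Spearman screen against the MPC1/MPC2 anchors; alignment with
   published prognostic signatures; and a pan-cancer loop that omits
   datasets without ≥ 75% homogeneous core clusters.

The statistical primitives (Fisher exact, hypergeometric tail, exact
Wilcoxon rank-sum, Benjamini-Hochberg, Kaplan-Meier, log-rank) are
implemented in the package and tested against brute-force enumeration
oracles and independent libraries.

## Worked example

`examples/01_simulate_and_subtype.py` simulates a 600-sample two-cohort
dataset with the published subtype mixing proportions (54/27/11/8%),
writes it to disk, and runs the full file-based pipeline:

```
samples analysed: 579 (excluded 21 with purity < 30%)

assigned subtype counts:
subtype
quiescent          295
cholesterogenic    150
glycolytic          69
mixed               65

truth vs assigned:
subtype          cholesterogenic  glycolytic  mixed  quiescent
truth
cholesterogenic              150           0      3          0
glycolytic                     0          57      0          0
mixed                          0           0     62          0
quiescent                      0          12      0        295

adjusted Rand index vs planted truth: 0.937
```

579 of 600 samples survive the purity filter; the quadrant rule recovers
the planted phenotypes almost perfectly (ARI 0.94), and the recovered
group sizes mirror the planted mixing proportions. The remaining
examples cover survival contrasts (`02`), CNV enrichment (`03`), the
MPC1/MPC2 correlation screen (`04`), signature alignment (`05`) and the
pan-cancer homogeneity filter (`06`); each prints its numbers with a
short note on what they mean.

A thin CLI mirrors the pipeline stages:

```bash
glycochol simulate cohort/ --n-samples 600 --seed 0
glycochol all cohort/ results/ --k 2 --seed 0
```

## Layout

- `src/glycochol/` — the library: `io_formats` (TSV/GMT/SEG/BED readers
  and writers), `preprocess`, `cluster` (Ward.D2 + consensus),
  `subtyping`, `genomics`, `stats`, `survival`, `alignment`,
  `synthetic` (cohort generator), `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `tests/` — unit, property and acceptance suites with independent
  enumeration oracles in `tests/oracles.py`.
- `docs/methods.md` — the model, parameter and design notes.
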