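# Methods and design notes

## The classification model

Samples are classified in a two-dimensional metabolic score plane. For a
gene-by-sample matrix on the standardized scale (per-cohort, per-gene
z-scores), the glycolytic score of a sample is the median standardized
expression of the *core glycolytic* gene cluster and the cholesterogenic
score the median over the *core cholesterogenic* cluster; the four
subtypes are the quadrants of that plane with the boundary convention
"≤ 0 is low" on both axes. The zero threshold is only meaningful because
the scores are computed on a centered scale: after per-cohort gene-wise
z-scoring, 0 is the cohort-typical expression level, so "score > 0"
reads as "this pathway is expressed above the cohort norm".

Core clusters come from resampling consensus clustering of the
glycolytic + cholesterogenic gene union (items = genes, features =
samples; each repetition subsamples `ceil(p_item * n)` genes without
replacement, clusters with Ward.D2 at `k`, and the consensus matrix
records co-clustering fractions normalized by co-sampling counts).
Final gene clusters are obtained by Ward.D2 on `1 − M` treated as a
distance. A cluster qualifies as core cholesterogenic when more than 90%
of its annotated members are cholesterogenic, and as core glycolytic
when more than 30% are glycolytic; among several candidates the one with
the highest relevant fraction wins, with deterministic tie-breaks
(larger cluster, then lowest cluster id). The asymmetric thresholds
reflect that the cholesterogenic set (72 genes) tends to form large pure
clusters while the glycolytic set (29 genes) is more easily diluted.

### Ward.D2 from first principles

The agglomeration applies the Lance–Williams recurrence to *squared*
Euclidean distances and reports heights as the square root of the merge
cost — the Ward.D2 convention, which reproduces `hclust(method =
"ward.D2")` and SciPy's `linkage(..., "ward")` on Euclidean input (the
test suite asserts exact height agreement with SciPy). Ties in the
minimal merge cost are broken by the smallest (row, column) slot pair,
so every run is deterministic for a given input order. Cutting at `k`
undoes the last `k − 1` merges; labels are numbered by each cluster's
smallest member index.

## Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| purity threshold | 0.30 | samples with tumor content strictly below are excluded |
| log2 fold-change screen | 1.0 (inclusive) | differential-expression cut on the log2 scale |
| consensus `k` / `reps` / `p_item` / `p_feature` | 5 / 100 / 0.8 / 1.0 | published clustering settings |
| CNV calling | ≥ 10 probes, seg.mean > 0.2 / < −0.2 (strict), copy ≥ 3 / ≤ 1 (inclusive) | amplification / deletion rules |
| minimum survival | 1 month (inclusive) | samples below are dropped before survival analysis |
| pan-cancer floor / homogeneity | 100 samples / 0.75 (inclusive) | dataset screening rules |
| alpha | 0.05 (enrichment), 0.01 (correlation screen) | two-sided significance levels |

Segments without an integer copy-status column are called on probe count
and segment mean alone; when copy status is present both criteria must
hold. BED intervals are 0-based half-open; SEG rows are 1-based
inclusive on disk and converted on read; gene mapping requires ≥ 1 bp
overlap in half-open coordinates. The BH family for event enrichment is
all (gene × event class × subtype) tests jointly — the widest, most
conservative choice; a pooled "ANY" event class is tested alongside the
four primary classes because public mutation tables often mix variant
classes. Survival times are months; a reader switch converts days by
/30.44.

## Statistical primitives

Fisher's two-sided exact test sums, over tables with the observed
margins, the probabilities not exceeding the observed table's (with a
1e-7 relative slack against float round-off); probabilities are exact
rationals, so the test agrees with brute-force enumeration to machine
precision. The hypergeometric enrichment tail is the exact upper sum.
The Wilcoxon rank-sum p-value is exact by full enumeration whenever
`C(n, n_a) ≤ 20000` (which handles ties exactly), exact by the classic
count recursion when there are no ties and `min(n) ≤ 10`, and otherwise
uses the normal approximation with tie correction and no continuity
correction. Spearman's coefficient is the Pearson correlation of
mid-ranks; for n ≤ 9 its p-value is an exact permutation enumeration,
otherwise the t approximation. The log-rank statistic is the quadratic
form of (O − E) over the first k − 1 groups with the multivariate
hypergeometric covariance, χ² with k − 1 df; samples censored exactly at
an event time count as at risk for that event. Benjamini–Hochberg is the
standard min-monotone step-up capped at 1 — note it is *not* idempotent
(re-adjusting adjusted p-values inflates them further), so the tests
assert capping, dominance and order-statistic monotonicity instead.

## The synthetic cohort

The generator emulates a two-cohort bulk RNA-seq study of ~600 tumors:

- **Subtypes**: i.i.d. draws with mixing proportions (332, 164, 65, 49)/610
  for quiescent / cholesterogenic / glycolytic / mixed — the published
  subgroup sizes.
- **Expression**: formed on the log10 scale and exponentiated to
  pseudo-counts, so the full TPM → log10(TPM+1) → z-score path exercises
  real normalization behaviour. Each metabolic block shares a latent
  per-sample pathway activity; the subtype shift `delta` (default 2.0,
  in units of the per-gene log-noise SD, default 0.35 ≈ a 5-fold change)
  acts on that activity in the samples where the pathway is active
  (glycolytic + mixed for the glycolytic block, cholesterogenic + mixed
  for the cholesterogenic block). `block_correlation` (default 0.5) is a
  covariance budget: the subtype signal contributes `delta² p (1 − p)`
  of between-gene covariance, and a residual activity term with variance
  `tau² = max(0, rho − delta² p (1 − p))` supplies any shortfall. At
  `delta = 0` the marginal within-block correlation is exactly `rho`;
  with strong shifts the subtype structure itself carries the
  co-expression, as it does in tumor cohorts where the pathway program
  *is* the co-regulation. The budget form is what makes the generator
  self-consistent: adding a full equicorrelated residual on top of the
  shifts would push the marginal correlation far above the configured
  value and drown the quadrant scores in block-level noise no analysis
  could remove.
- **Transcriptome size**: 29 + 72 metabolic genes over a background of
  5000 (containing MPC1, MPC2, MYC, TP53). The background is large so
  that pathway activation changes a sample's TPM denominator only
  marginally (< 0.03 SD compositional coupling), as in real data where
  these 101 genes are a negligible mass fraction of ~25k measured genes.
- **Batch structure**: a scalar per-cohort shift plus gene-specific
  per-cohort offsets (N(0, 0.3²) on the log SD scale). The scalar shift
  cancels under TPM (a uniform per-sample factor drops out of the
  denominator), so the gene-specific component is what the per-cohort
  z-scoring stage actually has to remove.
- **Survival**: exponential with baseline median 30 months (glycolytic
  reference) and multiplicative subtype hazards (cholesterogenic 2.0,
  quiescent 1.5, mixed 1.6, glycolytic 1.0); independent uniform
  censoring on [0, c] with c solved numerically so the marginal
  censoring fraction matches `censoring_rate` (default 0.3).
- **Copy number**: MYC-amplification and TP53-deletion segments planted
  with per-subtype probabilities (enriched in cholesterogenic samples),
  with cis effects on MYC/TP53 expression (+1 / −1 SD), plus
  copy-neutral background segments that exercise the caller's filters.
  MPC1 is elevated and MPC2 lowered (±1.5 SD) in glycolytic samples,
  with a smaller MPC2 elevation in cholesterogenic samples.
- **Purity**: Beta(4, 2), putting ≈ 3% of samples below the 0.30
  exclusion threshold so the filter is always exercised.
- **Randomness**: one RNG stream per component (genome layout,
  expression, survival, copy number, clinical/mutations), all derived
  from the master seed, so toggling one component leaves the others
  bit-identical.

What the generator does *not* model: read-level count noise (negative
binomial dispersion), gene-length biases beyond the synthetic BED,
copy-number breakpoint realism, germline variation, or realistic
correlation between the MPC anchors and the rest of the transcriptome.
Passing tests therefore demonstrate that the pipeline recovers the
planted structure under a faithful statistical abstraction of the study
design, not that it would reproduce any specific cohort's numbers.

## The recovery benchmark runs at k = 2

The pipeline default is k = 5, the published clustering depth for real
cohorts whose metabolic sets decompose into finer co-expression
sub-modules. The synthetic generator, however, plants exactly two
modules, so the planted-label recovery benchmark (acceptance test and
`examples/01`) clusters at k = 2 — the depth matched to the structure
being recovered, which is how a practitioner would set k after
inspecting the consensus matrix. At k = 5 on two planted modules the
hierarchy must split the pure 29-gene glycolytic block, the selected
core shrinks to ~11–19 genes, and the median score noise grows by
`sqrt(29/m)`; that inflates the quiescent/glycolytic boundary error for
any generator with these effect sizes — a property of the decision rule
at mismatched k, not of the implementation.

## Degenerate inputs and numerical choices

Constant genes standardize to 0 with a warning; gene pairs never
co-sampled get consensus 0 with a warning; median of an even number of
core genes is the mean of the two middle values; purity exactly at the
threshold is retained, survival exactly at 1 month is retained,
homogeneity exactly 0.75 is retained, a log2 fold change exactly at the
threshold is included — every published boundary keeps its stated
strict/inclusive sense and is unit-tested. Consensus matrices are
validated (symmetry, unit diagonal for sampled items, [0, 1] range) on
every construction. File writers emit 17 significant digits and readers
parse with round-trip float precision, so write∘read is the identity.

## Known limitations

- The "semi-automatic" assignment step of published classifier schemes
  is operationalized as cluster-then-label-by-signed-centroid — a
  deterministic, reproducible stand-in for a manual step, not a
  reconstruction of any original procedure; the three published
  signature gene lists are not shipped (user-supplied GMT, with
  synthetic stand-ins in tests and examples).
- Cluster-count selection is manual; consensus CDF/PAC diagnostics are
  not implemented as a decision rule.
- No empirical-Bayes batch correction (per-cohort z-scoring only) and no
  tumor-purity estimation (purity is an input column).
- Survival modeling is limited to Kaplan-Meier and log-rank; no Cox
  regression, no per-gene cutoff optimization.
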