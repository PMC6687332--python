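# Methods

## Scope and data model

The package analyses a three-condition (lean / obese / CR) droplet
scRNA-seq experiment downstream of alignment, UMI counting, integration
and clustering: its inputs are a genes × cells integer UMI matrix
(MatrixMarket triplet with gene/barcode sidecars, or dense CSV) and a
per-cell table with condition and cluster labels. In memory, data live in
an `AnnData` (cells × genes, sparse counts in `.X`, normalized values in
`layers["lognorm"]`, per-cell QC in `.obs`). Upstream steps — read
alignment, multi-sample integration, graph clustering, cell-type
annotation — are out of scope and consumed as given labels.

## Quality control

Per cell we compute the UMI total and the mitochondrial fraction (genes
with the `mt-` prefix). "Low-quality" is operationalised one-sidedly, as
in common droplet QC practice: a cell fails if a metric exceeds

    median + k · 1.4826 · MAD,   k = 3 (default)

computed **within its condition sample**, since each 10x run has its own
depth distribution. High mitochondrial fraction marks apoptotic cells;
high UMI total marks likely doublets. Low-depth cells are deliberately not
removed (only all-zero cells fail trivially). If the MAD is zero and all
values equal, nothing fails on that metric. Clusters in which fewer than
5% of cells detect CD45 (*Ptprc*) are excluded as non-hematopoietic
contamination; the rule is a strict less-than, so a cluster exactly at the
cutoff is retained. Normalization is `ln(1 + 10⁴ · count / depth)`
(natural log, pseudocount 1), which preserves zeros and is invariant to
per-cell depth scaling.

## Differential expression

For each cluster and ordered condition pair, every gene is tested with the
two-sided Wilcoxon rank-sum test on normalized values: exact enumeration
when `min(n_a, n_b) ≤ 8` and the data are untied, otherwise the normal
approximation with midrank tie correction and continuity correction (a
vectorised implementation is used for large groups and is tested to match
the scalar path to 10 significant digits). P-values are BH-adjusted within
each (cluster, contrast) family — mirroring per-cluster reporting — not
globally. `logFC = ln((mean_a + 1)/(mean_b + 1))` on de-logged normalized
group means; because `expm1(ln(1+x)) = x`, these means are exactly
`mean(10⁴ · count/depth)`. No gene is pre-filtered by fold change or
detection rate, so fold changes remain available in clusters that lack
power. A contrast with fewer than 3 cells in either group is NotAssessed —
this is how the absent-in-lean cluster propagates through the pipeline.
Marker genes (one-vs-rest per cluster) must be detected in ≥ 25% of the
cluster's cells, have positive logFC and adjusted p < 0.05; whether the
original marker definition imposed a significance cutoff is not specified
anywhere we could verify, so α = 0.05 is applied and stated.

## Recovery stratification

The classifier takes per-cluster condition means (L, O, C) on the
de-logged normalized scale and applies, in order:

1. **Different** — C outside `[min(L,O), max(L,O)]` and
   `relDiff(C, L) > τ` and `relDiff(C, O) > τ`, with τ = 0.10 and
   `relDiff(C, X) = |C − X| / max(X, ε)`, ε = 10⁻⁶;
2. **Recovered** — `|C − L| < |C − O|`;
3. **NotRecovered** — otherwise, including exact ties (conservative
   toward claiming recovery).

Design choices that were genuinely open, and how we resolved them:

* **Scale.** The 10% rule is applied to relative differences of de-logged
  mean expression — the same scale as the fold-change means — keeping
  "10% different" interpretable as relative expression change. An absolute
  or log-scale reading would be defensible; the relative reading is
  documented and parameterised (τ).
* **Precedence.** A non-intermediate C far from both references is
  Different even though it is also strictly closer to one side; Different
  is its own class, not a refinement of the other two.
* **Denominator.** Recovered/NotRecovered/Different fractions are
  reported per cluster over genes DE in obese-vs-lean within that cluster
  (`obese_de_only`, default) or over all selected genes (`all_selected`);
  the two readings of "genes differentially expressed in obese tissue"
  are both available.
* The ε floor prevents division blow-up for silent genes; scale
  invariance `classify(sL, sO, sC) = classify(L, O, C)` holds whenever
  all scaled means stay above ε.

The same rule applied to cluster proportion triples yields composition
trajectories (RevertedToLean / RemainedShifted / UniqueToCR), with an
Unchanged class when `|p_obese − p_lean| / max(p_lean, ε) ≤ τ`.

## Coordinated fold-change analysis

Genes with `|logFC| ≥ ln(1.5)` **and** adjusted p < α in at least one
cluster of the obese-vs-lean contrast form the rows of a genes × clusters
logFC matrix (entries unthresholded; NotAssessed clusters are NaN). The
significance requirement in the triggering cluster keeps noise-only large
folds in tiny clusters out of the matrix. Rows are ordered by
agglomerative hierarchical clustering — complete linkage on Euclidean
distances by default, both configurable — chosen because they are
deterministic and oracle-checkable against a textbook quadratic
implementation. NaNs are imputed as 0 for clustering and flagged;
constant rows under the correlation metric are set aside as singletons.

## Enrichment

Over-representation of a target list against a background universe (all
detectably expressed genes) uses the one-sided upper-tail hypergeometric
test, `p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`, BH-adjusted across
sets — the standard target-vs-background mode. Gene sets are user-supplied
GMT; no ontology snapshot is bundled because term databases are versioned
and their counts are not reproducible. No threshold optimisation, DAG
propagation or pathway topology is attempted. For recovery categories the
per-set fraction of category genes is reported alongside p-values.

## Synthetic data generator

The generator emulates the structure of a three-condition VAT leukocyte
atlas so that every downstream stage can be validated against planted
truth.

* **Counts.** Negative binomial via gamma–Poisson: gene mean =
  size factor × per-gene cluster/condition mean; size parameter r = 10
  (biological CV ≈ 1/√r ≈ 0.32, typical of UMI data). Size factors are
  log-normal with σ = 0.3, normalised to unit mean so empirical means are
  unbiased estimates of planted means.
* **Scale.** Defaults mirror the study: 2268 / 5232 / 2458 cells in
  lean / obese / CR, 15 clusters, one cluster (c02) absent in lean and
  expanding from 7% (obese) to 30% (CR) of cells, the dominant cluster
  c01 following 16% → 38% → 17%. 2000 genes — a typical variable-gene
  panel size, since the DE stage of such workflows runs on variable
  genes. Tests and the acceptance script use a reduced configuration
  (5 clusters, ≈ 200 cells per cluster-condition, c02 at 0/10/30%) for
  speed; the problem sizes are stated with each result.
* **Cluster identity.** Cells are allocated to clusters by
  largest-remainder rounding of the proportion vectors (exact totals,
  exactly zero cells for zero-proportion clusters); each cluster gets 8
  marker genes boosted 8-fold in all conditions.
* **Planted effects.** 100 genes per category (Recovered, NotRecovered,
  Different) at a 2-fold obese-vs-lean effect, with base means drawn
  log-uniform from [2, 8] counts/cell — emulating the well-detected
  variable genes on which DE operates. Effects are planted in
  **mass-balanced pairs**: an up-regulated gene with base mean m is paired
  with a down-regulated gene with base mean m·fold, and Different genes
  sit above both references in the up member and below both in the down
  member (divergence 1.25, constrained to (1.1, (1+fold)/fold]). This
  makes the expected library size identical in all three conditions —
  without it, depth normalization converts composition shifts into
  spurious condition effects on every gene, null genes stop being null,
  and the classifier is systematically biased. Planted triples satisfy
  their category under the classifier by construction (tested at 100%).
* **Outliers.** High-mito cells have mitochondrial counts inflated to
  ~60% of the library (far above 5× the cohort median); doublets are
  element-wise sums of two same-condition cells drawn from above the 60th
  depth percentile — the detectable two-cells-in-one-droplet motif that
  UMI filtering targets — appended as new barcodes with parents recorded.

**What the generator does not emulate:** ambient RNA, batch/chemistry
effects, integration artifacts, cluster-specific condition responses
(planted effects are shared across clusters), gene–gene correlation
beyond the compositional constraint, low-depth failed cells, or realistic
transcriptome-wide expression (it is a variable-gene panel). Passing
tests therefore demonstrate correctness of the statistical machinery and
end-to-end plumbing under a faithful null/effect structure — not
robustness to the full messiness of real tissue data.

## Numerical and degenerate-input conventions

* Wilcoxon with zero rank variance (all values tied) returns p = 1.
* BH adjustment caps at 1 and preserves input order.
* `fold ≥ ln(1.5)` row inclusion is inclusive at the boundary; the CD45
  detection cutoff is exclusive (strict less-than) at the boundary.
* Classifier ties (|C−L| = |C−O|) → NotRecovered; means are validated
  nonnegative.
* Empty gene sets, empty recovery tables, clusters with no assessed
  genes, conditions with zero cells, and GMT lines with too few fields
  raise or warn explicitly rather than propagating NaNs.
* Determinism: a `SimConfig` (including seed) fully determines the
  dataset; derived random streams (outlier planting, decoy gene sets) use
  seed sequences spawned from the same seed.

## Known limitations

* Recovery fractions depend on the chosen τ and on the expression scale;
  both are package conventions, not universal definitions.
* BH is applied within (cluster, contrast) families; gene selection
  across families does not control a global FDR.
* The composition-trajectory rule is a reconstruction — upstream
  descriptions of "reverted" and "unique" proportions are verbal, and any
  numeric rule (including this one) is a design choice.
* No statistical inference is attached to composition shifts; scRNA-seq
  cell counts estimate proportions with compositional, not multinomial,
  uncertainty.
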