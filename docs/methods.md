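# Methods

## Model and procedure

The pipeline treats a non-negative gene-by-sample expression matrix *A*
(TPM by default; raw counts and log2(TPM+1) are supported and tagged
explicitly) as approximately low-rank: *A* ≈ *WH* with *W* ≥ 0 the
gene-by-metagene basis and *H* ≥ 0 the metagene-by-sample coefficients.
The factorization is fitted by minimizing the generalized KL divergence
with the standard multiplicative updates

    H ← H ⊙ (Wᵀ(A ⊘ WH)) ⊘ (Wᵀ1),    W ← W ⊙ ((A ⊘ WH)Hᵀ) ⊘ (1Hᵀ)

which never produce negative entries and never increase the objective.
Samples are clustered by the largest entry of their *H* column (ties to
the lowest metagene index). The underlying assumptions are the usual ones
for NMF on expression data: expression profiles are approximately additive
mixtures of a small number of non-negative latent programs, and the
disease phenotype is dominated by one such program.

With two groups the sample clusters are identified against the phenotype
labels: the cluster with the larger disease fraction is *g₊*, its disease
fraction is the precision *p*, and gene *i* receives
`p·W[i,g₊] + (1−p)·W[i,g₋]` — a convex combination of the gene's basis
weights, weighted by how cleanly the factorization isolated the disease
group. With a pure disease cluster (*p* = 1) the ranking is exactly the
disease-metagene weight; with an impure cluster the normal metagene
contributes proportionally. Labeling and scoring are deliberately
restricted to *k* = 2 (disease vs normal); subtype-style analyses at
*k* > 2 are out of scope and raise an error. Scores are computed from the
best (lowest final divergence) of the consensus runs. A tie in the
cluster disease fractions is refused rather than resolved silently.

## Numerical choices

* Initialization: `W`, `H` i.i.d. uniform(0,1) × √(mean(*A*)/k), seeded;
  every run is bit-reproducible from its seed.
* Epsilon flooring at 1e-12 on `W`, `H` and the `WH` denominator prevents
  division by zero and log of zero; consequently all factor entries are
  strictly positive.
* Stopping: at most `max_iter` = 2000 iterations, or earlier when the
  relative change in the divergence stays below `tol` = 1e-6 for 10
  consecutive checks (the objective is evaluated every 10 iterations).
* Natural logarithm in the divergence. Only monotonicity and minima
  matter downstream, not the absolute scale.
* The divergence trace is recorded at each check and is non-increasing to
  a relative tolerance of 1e-8 (the flooring can introduce sub-1e-8
  wobble).
* Degenerate inputs: an all-zero matrix, a rank ≥ min(*N*, *M*), missing
  or negative entries, unlabeled samples, and a zero-size gene list all
  raise immediately with the offending items named.

## Rank selection

For each candidate rank, `n_runs` independently initialized fits (default
100; seeds `base_seed … base_seed + n_runs − 1`) yield binary sample
co-clustering (connectivity) matrices whose average is the consensus
matrix. Diagnostics per rank:

* **Cophenetic correlation** — Pearson correlation between the consensus
  distances 1 − *c* and the ultrametric distances of their average-linkage
  hierarchy (scipy `linkage`/`cophenet`). Undefined (NaN, with a warning)
  when the consensus is constant.
* **Dispersion** — Kim–Park form `(1/M²) Σ 4(c−½)²`; 1 iff the consensus
  is binary. The literature names this coefficient without always printing
  the formula; this canonical form is used.
* **Silhouette** — mean silhouette width on distance 1 − *c* with the
  partition from cutting the average-linkage tree into `rank` clusters.
  Average linkage is used throughout; it is the customary choice for
  consensus matrices, and the cross-checked brute-force oracles in the
  test suite pin this behavior down.
* Explained variance `1 − ‖A−WH‖²/‖A‖²` and the best/mean final
  divergence are reported as residual diagnostics.

The default selection rule is the smallest rank attaining the maximum
cophenetic coefficient; all metrics are emitted so a multi-metric
judgment can override it. Multi-run consensus is the only supported mode
(`n_runs ≥ 2`), since a consensus over one run is meaningless.

## Enrichment benchmarking

`matched_comparison` mirrors reference-set benchmarking practice: each
threshold in the grid (defaults: FDR < 0.05/0.01 crossed with no cut and
|log₂FC| > 0.5/1/1.5) defines a DEG list of size *n*; the same *n* top
scored genes are taken from the ranking, so both methods are compared at
matched list size. Ratios are carried unrounded; rounding to 2 decimals is
presentation-only. The universe *N* defaults to the number of genes
surviving the expression filter. Thresholds selecting zero genes are
excluded from the means with a warning. The two ratio columns are compared
with Welch's unequal-variance two-sample t-test: on the published cohort
tables this reproduces the printed significance values, whereas paired or
pooled-variance variants do not, which is why Welch is the fixed choice.

Gene identifiers are matched case-insensitively after whitespace trimming,
because mouse symbols (e.g. Lyz2) and reference lists compiled from
human-centric databases differ in casing.

`simple_de_test` (per-gene Welch t-test on the log2(x+1) scale with
Benjamini–Hochberg adjustment) is a documented convenience comparator
only; it is not limma-voom, and analyses aiming to reproduce published
DEG counts should supply the original DE table via `--de`.

A normalized-entropy score (`kim_entropy_score`, the Kim–Park style
subtype scheme: `1 + (1/log₂k) Σ q log₂ q` on row-normalized basis
weights) is provided as a comparator, and `correlation_summary` reports
the fraction of highly correlated pairs within a top gene list.

## Synthetic data

`generate_dataset` plants ground truth where the score looks — in the
basis matrix — and emulates a two-group bulk RNA-seq cohort:

* Baseline gene expression is heavy-tailed lognormal (log-mean 1.5,
  log-sd 1.2; TPM-like medians with a long upper tail).
* 50 marker genes (the planted reference set) receive a 4× baseline boost
  (disease-associated genes tend to be well expressed in the affected
  tissue) and a `marker_effect` = 3 multiplicative elevation in the
  disease metagene. A `null_marker_fraction` = 0.4 of markers keeps
  effect 1: disease-associated genes with negligible fold change, which
  real cohorts contain in quantity and which no fold-change threshold can
  recover.
* 200 "bystander" genes outside the reference set receive genuine
  disease-metagene fold changes (gamma-distributed |log₂FC|, mean ≈ 1.2,
  10% down-regulated), emulating secondary/downstream expression shifts.
  They dilute DEG lists exactly the way non-reference DE genes dilute
  published reference-set benchmarks.
* `H` has a two-block structure with per-sample activity jitter
  (uniform 0.8–1.2) and a small cross-program level (0.04).
  `mislabel_fraction` swaps the profile of that fraction of samples on
  *both* sides (disease-labeled samples with normal-like profiles and
  vice versa), emulating cohorts where the phenotype is not yet
  expressed; this makes the realized cluster precision fall below 1.
* Noise is multiplicative gamma with unit mean (CV = `noise_scale`,
  default 0.1), keeping the matrix continuous and non-negative; a Poisson
  option produces count-like data.

Defaults (2,000 genes, 60 samples, 20 diseased) are a mid-sized cohort on
which the full pipeline runs in seconds; tests run the consensus survey at
20 runs/rank and the ten-seed end-to-end recovery at 3 runs/seed, which
the separation of the planted structure makes sufficient. What the
generator does *not* emulate: library-size variation, gene–gene
correlation beyond the two planted programs, batch effects, count
overdispersion calibrated to real data, or any organism-specific biology.
Passing recovery tests therefore demonstrates correctness of the
machinery under the planted model, not performance on real cohorts.

## Known limitations

* Scoring assumes one disease program; heterogeneous diseases with
  several expression subtypes violate the *k* = 2 restriction.
* The score inherits the expression-magnitude scale of *W*: highly
  expressed genes dominate the top of the ranking. This is intrinsic to
  basis-weight scoring and is the reason the enrichment benchmark, not
  the raw ranking, is the comparison instrument.
* KL multiplicative updates converge to local minima; the multi-restart
  consensus mitigates but does not eliminate initialization dependence.
* The enrichment ratio treats the reference set as ground truth;
  non-reference genes in a list are not necessarily false positives when
  the reference set is incomplete.
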