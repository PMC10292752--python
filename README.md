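# nmfmarker

Metagene-based gene scoring for disease-marker discovery from bulk RNA-seq
expression matrices, with an enrichment-ratio framework for benchmarking
ranked gene lists against a curated disease reference set.

The package is aimed at transcriptomics analysts who have a two-group
(disease vs normal) expression cohort and a list of genes already known to
be associated with the disease, and who want to rank all genes by disease
relevance in a way that is not limited by hard fold-change / FDR cut-offs.

## Method

Given a non-negative gene-by-sample matrix *A* (*N* × *M*), KL-divergence
NMF finds non-negative *W* (*N* × *k*) and *H* (*k* × *M*) with *A* ≈ *WH*
by minimizing the generalized Kullback–Leibler divergence

    D(A ‖ WH) = Σᵢⱼ [ Aᵢⱼ log(Aᵢⱼ/(WH)ᵢⱼ) − Aᵢⱼ + (WH)ᵢⱼ ]

with the classic multiplicative update rules. Columns of *W* are
*metagenes*; sample *j* is assigned to cluster argmaxᵢ *H*ᵢⱼ. The rank *k*
is chosen from consensus-clustering diagnostics over many random restarts
(cophenetic correlation, Kim–Park dispersion, consensus silhouette,
explained variance, residual divergence).

At *k* = 2 the cluster with the larger fraction of disease-labeled samples
is the disease cluster *g₊* with precision *p* (fraction of disease samples
among its members), and each gene *i* is scored

    scoreᵢ = p · W[i, g₊] + (1 − p) · W[i, g₋]

Genes are ranked by descending score. To benchmark the ranking, a grid of
DEG significance thresholds (adjusted *p* and |log₂FC|) defines list sizes
*n*; for each threshold the DEG list and the top-*n* scored genes are
compared through the enrichment ratio

    ER = (g/n) / (G/N)

where *g* is the list's overlap with the *G*-gene reference set and *N* is
the analysis universe. Column means are compared with Welch's t-test.

The main entry points are scikit-learn style estimators — `KLNMF`,
`ConsensusNMF` and `NMFGeneScorer` (`fit`, fitted attributes, `get_params`)
— with plain functions (`nmf_fit`, `consensus_run`, `rank_survey`,
`score_genes`, `matched_comparison`, …) as thin wrappers, plus a
`nmfmarker` command-line tool.

## Worked example

Generate a planted-marker synthetic cohort (2,000 genes, 60 samples of
which 20 diseased, 50 reference markers) and run the full pipeline:

```sh
nmfmarker simulate --out-dir demo --genes 2000 --samples 60 \
    --disease 20 --markers 50 --seed 7
nmfmarker run-all --matrix demo/matrix.tsv --labels demo/labels.tsv \
    --reference demo/reference.txt --out-dir demo/run \
    --ranks 2:4 --runs 10 --seed 42
```

The rank survey (`demo/run/rank_metrics.tsv`) shows a perfectly stable
two-cluster solution — consensus entries all 0/1, so cophenetic,
dispersion and silhouette are exactly 1 at rank 2 and lower at 3–4:

```
rank  cophenetic  dispersion  silhouette  explained_variance
2     1.0000      1.0000      1.0000      0.9896
3     0.9990      0.8838      0.8092      0.9915
4     0.9953      0.7842      0.5971      0.9924
```

The disease cluster is recovered with precision 1.0, so each gene's score
equals its disease-metagene basis weight, and the matched-size comparison
(`demo/run/enrichment_table.tsv`) prints:

```
             threshold   n  g_deg  ratio_deg  g_nmf  ratio_nmf
              FDR<0.05 220     30   5.454545     35   6.363636
  FDR<0.05 & |logFC|>1  91     29  12.747253     22   9.670330
              FDR<0.01 219     30   5.479452     35   6.392694
  FDR<0.01 & |logFC|>1  91     29  12.747253     22   9.670330
FDR<0.05 & |logFC|>0.5 164     30   7.317073     30   7.317073
FDR<0.05 & |logFC|>1.5  29      0   0.000000      8  11.034483
FDR<0.01 & |logFC|>0.5 164     30   7.317073     30   7.317073
FDR<0.01 & |logFC|>1.5  29      0   0.000000      8  11.034483
mean ratio DEG 6.38 vs NMF 8.60 (p=0.262)
```

Reading the numbers: the DEG lists contain the 30 markers that carry a
genuine fold change plus many non-reference "bystander" DE genes, while
the 20 planted markers *without* a fold change are invisible to every
threshold (the 0-overlap rows are thresholds the diluted fold changes
cannot pass). The score ranking also recovers markers with no expression
change — hence the higher mean enrichment ratio — because they still carry
high disease-metagene weight. `summary.json` holds the same summary
machine-readably.

The same stages are available individually as `nmfmarker rank-survey`,
`nmfmarker score` and `nmfmarker compare`; `compare` accepts an external
differential-expression table (e.g. limma-voom output) via `--de`.

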