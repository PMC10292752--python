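"""Precision-weighted metagene gene scoring.

After a rank-2 factorization clusters the samples, the cluster with the
larger fraction of disease samples is labeled the disease cluster ``g+`` and
its purity is the precision ``p``.  Each gene ``i`` is then scored from the
basis matrix as

    score_i = p * W[i, g+] + (1 - p) * W[i, g-]

a convex combination of the gene's weight in the disease and normal
metagenes; genes are ranked by descending score.  A normalized-entropy
comparator score (the subtype-oriented scheme of Kim and Park) and a pairwise
correlation summary for top gene lists are provided as secondary analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .consensus import consensus_run
from .io import DISEASE, NORMAL
from .matrix import ExpressionMatrix, normalize_gene_id
from .nmf import Factorization, assign_clusters


@dataclass
class ClusterLabeling:
    """Disease/normal identity of the two sample clusters and the precision."""

    disease_cluster: int
    normal_cluster: int
    precision: float
    composition: dict[int, dict[str, int]]  # cluster -> {"disease": n, "normal": n}

    def to_dict(self) -> dict:
        return {
            "disease_cluster": int(self.disease_cluster),
            "normal_cluster": int(self.normal_cluster),
            "precision": float(self.precision),
            "composition": {
                str(k): {g: int(n) for g, n in v.items()}
                for k, v in self.composition.items()
            },
        }


def _labels_per_sample(labels, sample_ids: Sequence[str]) -> list[str]:
    if isinstance(labels, Mapping):
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValueError(
                f"unlabeled samples (exclude them upstream): {missing[:10]}"
            )
        out = [labels[s] for s in sample_ids]
    else:
        out = list(labels)
        if len(out) != len(sample_ids):
            raise ValueError("labels length does not match number of samples")
    bad = sorted({g for g in out if g not in (DISEASE, NORMAL)})
    if bad:
        raise ValueError(f"labels must be 'disease'/'normal', got {bad}")
    return out


def label_clusters(assignments, labels, sample_ids: Sequence[str] | None = None) -> ClusterLabeling:
    """Identify the disease cluster of a two-cluster sample partition.

    The disease cluster is the one with the larger fraction of
    disease-labeled samples among its members; the precision ``p`` is that
    fraction.  An empty cluster or a tie in the fractions raises
    ``ValueError`` (a tie demands manual assignment).

    Parameters
    ----------
    assignments : sequence of int
        Cluster index per sample; exactly two distinct clusters expected.
    labels : mapping sample_id -> group, or sequence of groups
        Groups are ``"disease"`` / ``"normal"``.  When a mapping is given,
        ``sample_ids`` supplies the sample order of ``assignments``.
    """
    a = np.asarray(assignments)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(a.size)]
    groups = _labels_per_sample(labels, sample_ids)
    clusters = np.unique(a)
    if clusters.size != 2:
        raise ValueError(
            f"labeling requires exactly 2 clusters, got {clusters.size} "
            "(rank-2 factorizations only)"
        )
    comp: dict[int, dict[str, int]] = {}
    frac: dict[int, float] = {}
    for c in clusters:
        members = [g for g, ci in zip(groups, a) if ci == c]
        if not members:
            raise ValueError(f"cluster {c} has no samples")
        n_dis = sum(1 for g in members if g == DISEASE)
        comp[int(c)] = {DISEASE: n_dis, NORMAL: len(members) - n_dis}
        frac[int(c)] = n_dis / len(members)
    c0, c1 = (int(c) for c in clusters)
    if frac[c0] == frac[c1]:
        raise ValueError(
            f"tie: both clusters have disease fraction {frac[c0]:.3f}; "
            "assign the disease cluster manually"
        )
    g_plus = c0 if frac[c0] > frac[c1] else c1
    g_minus = c1 if g_plus == c0 else c0
    return ClusterLabeling(
        disease_cluster=g_plus,
        normal_cluster=g_minus,
        precision=frac[g_plus],
        composition=comp,
    )


def gene_score(w_plus: float, w_minus: float, p: float) -> float:
    """Precision-weighted basis score ``p * W[i,g+] + (1 - p) * W[i,g-]``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"precision must be in [0, 1], got {p}")
    if w_plus < 0 or w_minus < 0:
        raise ValueError("basis entries must be non-negative")
    return p * w_plus + (1.0 - p) * w_minus


def score_genes(
    f: Factorization,
    labeling: ClusterLabeling,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score and rank all genes from a factorization's basis matrix.

    Cluster index ``c`` corresponds to basis column ``c`` of ``W`` (the same
    index used by the argmax on ``H``).  Returns a DataFrame with columns
    ``gene``, ``score``, ``W_plus``, ``W_minus`` sorted by descending score,
    ties broken by gene id ascending.  The labeling is attached under
    ``.attrs["labeling"]``.
    """
    W = f.W
    for c in (labeling.disease_cluster, labeling.normal_cluster):
        if not 0 <= c < W.shape[1]:
            raise ValueError(f"cluster index {c} is not a metagene column of W")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(W.shape[0])]
    if len(gene_ids) != W.shape[0]:
        raise ValueError("gene_ids length does not match W rows")
    p = labeling.precision
    w_plus = W[:, labeling.disease_cluster]
    w_minus = W[:, labeling.normal_cluster]
    table = pd.DataFrame(
        {
            "gene": [str(g) for g in gene_ids],
            "score": p * w_plus + (1.0 - p) * w_minus,
            "W_plus": w_plus,
            "W_minus": w_minus,
        }
    )
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["labeling"] = labeling
    return table


def top_genes(score_table: pd.DataFrame, n: int) -> list[str]:
    """First ``n`` gene ids of the descending score table."""
    if not 1 <= n <= len(score_table):
        raise ValueError(f"n must be in [1, {len(score_table)}], got {n}")
    return score_table["gene"].head(n).tolist()


def kim_entropy_score(W, k: int | None = None) -> np.ndarray:
    """Normalized-entropy comparator score per gene (Kim-Park style).

    With row-normalized basis weights ``q_j = W_ij / sum_j W_ij``:
    ``score_i = 1 + (1/log2 k) * sum_j q_j log2 q_j`` (0*log 0 = 0), in
    [0, 1]; 1 means all basis mass in one metagene, 0 means uniform spread.
    Rows summing to zero yield NaN and a warning.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    if k is None:
        k = W.shape[1]
    rowsum = W.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero W rows scored as NaN",
                      UserWarning, stacklevel=2)
    q = W / np.where(zero, 1.0, rowsum)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
    score = 1.0 + plogp.sum(axis=1) / np.log2(k)
    score[zero] = np.nan
    return score


def correlation_summary(
    m: ExpressionMatrix, genes: Sequence[str], threshold: float = 0.75
) -> tuple[float, float]:
    """Pairwise Pearson correlation summary of a gene list.

    Over all unordered pairs of the listed genes present in the matrix,
    returns ``(fraction of |r| > threshold, mean |r|)``.  Zero-variance genes
    are excluded with a warning.
    """
    lookup = {normalize_gene_id(g): g for g in m.gene_ids}
    present = [lookup[normalize_gene_id(g)] for g in genes
               if normalize_gene_id(g) in lookup]
    if len(present) < 2:
        raise ValueError("need at least 2 listed genes present in the matrix")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    sub = m.data.loc[present].to_numpy(dtype=float)
    var = sub.var(axis=1)
    if (var == 0).any():
        dropped = [g for g, v in zip(present, var) if v == 0]
        warnings.warn(f"zero-variance genes excluded: {dropped[:10]}",
                      UserWarning, stacklevel=2)
        sub = sub[var > 0]
        if sub.shape[0] < 2:
            raise ValueError("fewer than 2 genes with variance remain")
    r = np.corrcoef(sub)
    iu = np.triu_indices_from(r, k=1)
    absr = np.abs(r[iu])
    return float(np.mean(absr > threshold)), float(np.mean(absr))


class NMFGeneScorer(BaseEstimator):
    """End-to-end estimator: consensus KL-NMF, cluster labeling, gene scores.

    ``fit(X, y)`` takes a gene-by-sample matrix ``X`` (ExpressionMatrix or
    array) and per-sample group labels ``y`` (mapping or sequence of
    ``"disease"`` / ``"normal"``), runs ``n_runs`` rank-``n_components``
    factorizations, labels the clusters of the best (lowest-divergence) run
    against ``y``, and scores every gene.

    Attributes
    ----------
    factorization_ : Factorization
        Best run (lowest final KL divergence).
    labeling_ : ClusterLabeling
    precision_ : float
    scores_ : pandas.DataFrame
        Descending gene score table (gene, score, W_plus, W_minus).
    consensus_ : ndarray
        Consensus matrix of the runs (stability diagnostic).
    """

    def __init__(
        self,
        n_components: int = 2,
        n_runs: int = 100,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_components != 2:
            raise ValueError(
                "gene scoring requires a two-group (disease vs normal) "
                "rank-2 factorization; n_components > 2 is not supported"
            )
        if isinstance(X, ExpressionMatrix):
            gene_ids = X.gene_ids
            sample_ids = X.sample_ids
        else:
            X = np.asarray(X, dtype=float)
            gene_ids = [f"gene{i}" for i in range(X.shape[0])]
            sample_ids = [f"sample{j}" for j in range(X.shape[1])]
        res = consensus_run(
            X,
            rank=self.n_components,
            n_runs=self.n_runs,
            base_seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        f = res.best_run
        labeling = label_clusters(assign_clusters(f), y, sample_ids=sample_ids)
        self.consensus_result_ = res
        self.consensus_ = res.consensus
        self.factorization_ = f
        self.labeling_ = labeling
        self.precision_ = labeling.precision
        self.gene_ids_ = list(gene_ids)
        self.scores_ = score_genes(f, labeling, gene_ids=gene_ids)
        return self

    def top_genes(self, n: int) -> list[str]:
        return top_genes(self.scores_, n)
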