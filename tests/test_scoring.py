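"""Cluster labeling, precision-weighted gene scores, comparator scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmfmarker import (
    ExpressionMatrix,
    Factorization,
    NMFGeneScorer,
    correlation_summary,
    gene_score,
    kim_entropy_score,
    label_clusters,
    score_genes,
    top_genes,
)


def _assignments(cluster_sizes: dict[int, tuple[int, int]]):
    """Build (assignments, labels) from cluster -> (n_disease, n_normal)."""
    assignments, labels = [], []
    for cluster, (n_dis, n_norm) in cluster_sizes.items():
        assignments += [cluster] * (n_dis + n_norm)
        labels += ["disease"] * n_dis + ["normal"] * n_norm
    return np.array(assignments), labels


class TestLabelClusters:
    def test_pure_disease_cluster_precision_one(self):
        # cluster 0: 11/11 disease; cluster 1: 18 disease of 64
        assignments, labels = _assignments({0: (11, 0), 1: (18, 46)})
        lab = label_clusters(assignments, labels)
        assert lab.disease_cluster == 0
        assert lab.precision == pytest.approx(11 / 11)
        assert lab.composition[1] == {"disease": 18, "normal": 46}

    def test_mixed_clusters_pick_higher_fraction(self):
        # cluster 0: 11/32 disease; cluster 1: 11/26 disease
        assignments, labels = _assignments({0: (11, 21), 1: (11, 15)})
        lab = label_clusters(assignments, labels)
        assert lab.disease_cluster == 1
        assert lab.precision == pytest.approx(11 / 26)

    def test_tied_fractions_require_manual_assignment(self):
        assignments, labels = _assignments({0: (2, 2), 1: (3, 3)})
        with pytest.raises(ValueError, match="tie"):
            label_clusters(assignments, labels)

    def test_more_than_two_clusters_unsupported(self):
        assignments, labels = _assignments({0: (2, 0), 1: (0, 2), 2: (1, 1)})
        with pytest.raises(ValueError, match="2 clusters"):
            label_clusters(assignments, labels)

    def test_unlabeled_sample_refused(self):
        with pytest.raises(ValueError, match="unlabeled"):
            label_clusters([0, 1], {"s0": "disease"}, sample_ids=["s0", "s1"])


class TestGeneScore:
    def test_worked_example_full_precision(self):
        assert gene_score(20.64, 21.20, p=1.0) == pytest.approx(20.64, abs=1e-12)

    def test_equal_weights_collapse(self):
        assert gene_score(3.5, 3.5, p=0.5) == pytest.approx(3.5)

    def test_hand_computed_blend(self):
        assert gene_score(5.0, 10.0, p=0.8) == pytest.approx(6.0)

    def test_invalid_precision(self):
        with pytest.raises(ValueError, match="precision"):
            gene_score(1.0, 1.0, p=1.5)

    @given(
        w_plus=st.floats(0, 100, allow_nan=False),
        w_minus=st.floats(0, 100, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False),
    )
    def test_score_is_convex_combination(self, w_plus, w_minus, p):
        s = gene_score(w_plus, w_minus, p)
        assert min(w_plus, w_minus) - 1e-9 <= s <= max(w_plus, w_minus) + 1e-9


def _fact_from_W(W):
    W = np.asarray(W, dtype=float)
    return Factorization(W=W, H=np.ones((W.shape[1], 3)), rank=W.shape[1],
                         divergence_trace=[0.0])


def _labeling(p, g_plus=0):
    from nmfmarker import ClusterLabeling
    return ClusterLabeling(disease_cluster=g_plus, normal_cluster=1 - g_plus,
                           precision=p, composition={})


class TestScoreGenes:
    def test_full_precision_orders_by_disease_column(self, rng):
        W = rng.uniform(0.1, 10, (8, 2))
        table = score_genes(_fact_from_W(W), _labeling(1.0), gene_ids=list("abcdefgh"))
        expected = [list("abcdefgh")[i] for i in np.argsort(-W[:, 0], kind="stable")]
        assert list(table["gene"]) == expected

    def test_zero_precision_orders_by_normal_column(self, rng):
        W = rng.uniform(0.1, 10, (6, 2))
        table = score_genes(_fact_from_W(W), _labeling(0.0), gene_ids=list("abcdef"))
        expected = [list("abcdef")[i] for i in np.argsort(-W[:, 1], kind="stable")]
        assert list(table["gene"]) == expected

    def test_hand_computed_blended_scores(self):
        W = [[1.0, 9.0], [5.0, 5.0], [8.0, 2.0], [2.0, 2.0], [0.0, 10.0]]
        table = score_genes(_fact_from_W(W), _labeling(0.6), gene_ids=list("abcde"))
        by_gene = table.set_index("gene")["score"]
        for gene, (wp, wm) in zip("abcde", W):
            assert by_gene[gene] == pytest.approx(0.6 * wp + 0.4 * wm)
        assert list(table["gene"]) == ["c", "b", "a", "e", "d"]  # 5.6,5,4.2,4,2

    def test_score_recomputable_from_columns(self, rng):
        W = rng.uniform(0, 5, (10, 2))
        table = score_genes(_fact_from_W(W), _labeling(0.3))
        np.testing.assert_allclose(
            table["score"], 0.3 * table["W_plus"] + 0.7 * table["W_minus"]
        )

    def test_tied_scores_sorted_by_gene_id(self):
        W = [[2.0, 2.0], [2.0, 2.0], [1.0, 1.0]]
        table = score_genes(_fact_from_W(W), _labeling(0.5), gene_ids=["zz", "aa", "mm"])
        assert list(table["gene"]) == ["aa", "zz", "mm"]

    def test_invalid_cluster_column(self):
        with pytest.raises(ValueError, match="metagene column"):
            score_genes(_fact_from_W([[1.0, 2.0]]), _labeling(1.0, g_plus=5))


class TestTopGenes:
    def _table(self):
        return score_genes(_fact_from_W([[3.0, 0], [2.0, 0], [1.0, 0]]),
                           _labeling(1.0), gene_ids=["x", "y", "z"])

    def test_full_length(self):
        assert top_genes(self._table(), 3) == ["x", "y", "z"]

    def test_top_one(self):
        assert top_genes(self._table(), 1) == ["x"]

    def test_bounds(self):
        with pytest.raises(ValueError):
            top_genes(self._table(), 0)
        with pytest.raises(ValueError):
            top_genes(self._table(), 4)


class TestKimEntropyScore:
    def test_concentrated_row_scores_one(self):
        assert kim_entropy_score([[1.0, 0.0]], 2)[0] == pytest.approx(1.0)

    def test_uniform_row_scores_zero(self):
        assert kim_entropy_score([[0.5, 0.5]], 2)[0] == pytest.approx(0.0)

    def test_hand_computed_entropy(self):
        # 1 - H(0.75, 0.25) with H in bits
        h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert kim_entropy_score([[0.75, 0.25]], 2)[0] == pytest.approx(1 - h)
        assert kim_entropy_score([[0.75, 0.25]], 2)[0] == pytest.approx(0.1887, abs=5e-5)

    def test_zero_row_flagged_nan(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = kim_entropy_score([[0.0, 0.0], [1.0, 3.0]], 2)
        assert np.isnan(out[0]) and not np.isnan(out[1])

    def test_bounded_and_scale_invariant(self, rng):
        W = rng.uniform(0, 5, (20, 3))
        s1 = kim_entropy_score(W)
        assert ((s1 >= -1e-12) & (s1 <= 1 + 1e-12)).all()
        np.testing.assert_allclose(kim_entropy_score(W * 7.3), s1, atol=1e-12)


class TestCorrelationSummary:
    def _matrix(self, rows, genes):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=genes,
                         columns=[f"s{j}" for j in range(len(rows[0]))]),
            scale_tag="tpm",
        )

    def test_duplicated_profiles_fully_correlated(self):
        m = self._matrix([[1, 2, 3, 4], [1, 2, 3, 4]], ["a", "b"])
        frac, mean_r = correlation_summary(m, ["a", "b"], threshold=0.75)
        assert frac == 1.0 and mean_r == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # r = 4/5 = 0.8 by direct Pearson arithmetic
        m = self._matrix([[1, 2, 3, 4], [1, 3, 2, 4]], ["a", "b"])
        frac, mean_r = correlation_summary(m, ["a", "b"], threshold=0.75)
        assert mean_r == pytest.approx(0.8)
        assert frac == 1.0

    def test_threshold_one_excludes_noisy_pairs(self, rng):
        m = self._matrix(rng.uniform(1, 5, (4, 6)), list("abcd"))
        frac, _ = correlation_summary(m, list("abcd"), threshold=1.0)
        assert frac == 0.0

    def test_zero_variance_gene_excluded(self):
        m = self._matrix([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]], ["a", "b", "c"])
        with pytest.warns(UserWarning, match="zero-variance"):
            frac, mean_r = correlation_summary(m, ["a", "b", "c"])
        assert mean_r == pytest.approx(1.0)  # only the b-c pair remains


class TestNMFGeneScorer:
    def test_fit_recovers_planted_labeling(self, small_dataset):
        ds = small_dataset
        scorer = NMFGeneScorer(n_runs=3, max_iter=300, tol=1e-5, random_state=0)
        scorer.fit(ds.matrix, ds.labels)
        assert scorer.precision_ == pytest.approx(1.0)
        table = scorer.scores_
        p = scorer.precision_
        np.testing.assert_allclose(
            table["score"], p * table["W_plus"] + (1 - p) * table["W_minus"]
        )
        assert len(scorer.top_genes(5)) == 5

    def test_rank_above_two_unsupported(self, small_dataset):
        with pytest.raises(ValueError, match="not supported"):
            NMFGeneScorer(n_components=3).fit(small_dataset.matrix,
                                              small_dataset.labels)

    def test_sklearn_params_roundtrip(self):
        scorer = NMFGeneScorer(n_runs=7, random_state=3)
        assert NMFGeneScorer(**scorer.get_params()).get_params() == scorer.get_params()
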