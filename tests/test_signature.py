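"""AUC ranking, PLS classifier, nested LGOCV, nulls, metrics, cluster views."""

import numpy as np
import pytest

from bloodsig.core import ValidationError
from bloodsig.signature import (
    CVReport,
    compare_model_sizes,
    evaluate,
    fisher_lda_score,
    gene_auc_rank,
    hcluster_heatmap,
    nested_lgocv,
    pls_fit,
    pls_predict,
    random_geneset_null,
)
from .conftest import expr_from_log2, gaussian_matrix


def pairwise_auc_oracle(values, is_case):
    """Exhaustive pairwise-comparison AUC with half credit for ties."""
    pos = values[is_case]
    neg = values[~is_case]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRanking:
    def test_perfect_separator_ranks_first(self):
        y = np.vstack([[1, 2, 3, 10, 11, 12],
                       [5, 7, 6, 6, 5, 7.5]])
        x = expr_from_log2(y)
        labels = np.array([False] * 3 + [True] * 3)
        rank = gene_auc_rank(x, labels)
        assert rank.index[0] == "g0"
        assert rank["auc"].iloc[0] == 1.0

    def test_matches_pairwise_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            n_case = int(rng.integers(2, n - 1))
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, n_case, replace=False)] = True
            vals = rng.integers(0, 6, size=(5, n)).astype(float)  # force ties
            x = expr_from_log2(vals + 5)
            rank = gene_auc_rank(x, labels)
            for g in x.feature_ids:
                row = vals[x.feature_ids.index(g)] + 5
                assert rank.loc[g, "auc"] == pytest.approx(
                    pairwise_auc_oracle(row, labels))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(5, 9, (20, 14))
        labels = np.array([True] * 7 + [False] * 7)
        r1 = gene_auc_rank(expr_from_log2(y), labels)
        r2 = gene_auc_rank(expr_from_log2(np.exp(y / 3)), labels)
        assert list(r1.index) == list(r2.index)
        np.testing.assert_allclose(r1["auc"], r2["auc"], atol=1e-12)

    def test_ties_broken_lexicographically(self):
        y = np.vstack([[1, 2, 10, 11.0]] * 3)
        x = expr_from_log2(y, genes=["gb", "ga", "gc"])
        rank = gene_auc_rank(x, np.array([False, False, True, True]))
        assert list(rank.index) == ["ga", "gb", "gc"]


class TestPls:
    def test_univariate_single_component_equals_least_squares(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (30, 1))
        y = (rng.random(30) < 0.5).astype(float)
        pred = pls_predict(pls_fit(x, y, 1), x)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        np.testing.assert_allclose(pred, slope * x[:, 0] + intercept, atol=1e-9)

    def test_constant_class_code_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pls_fit(np.random.default_rng(0).normal(size=(10, 3)),
                    np.ones(10), 1)

    def test_separable_data_training_auc_one(self):
        rng = np.random.default_rng(3)
        y01 = np.array([0.0] * 20 + [1.0] * 20)
        x = rng.normal(0, 1, (40, 10))
        x[y01 == 1, :3] += 4.0
        model = pls_fit(x, y01, 3)
        scores = pls_predict(model, x)
        from bloodsig.signature import _auc
        assert _auc(scores, y01.astype(bool)) == 1.0

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(4)
        model = pls_fit(rng.normal(size=(50, 20)),
                        (rng.random(50) < 0.5).astype(float), 6)
        g = model.scores.T @ model.scores
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8

    def test_matches_sklearn_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 15))
        y = (rng.random(40) < 0.4).astype(float)
        mine = pls_predict(pls_fit(x, y, 5), x)
        ref = PLSRegression(n_components=5, scale=True).fit(x, y)
        np.testing.assert_allclose(mine, ref.predict(x).ravel(), atol=1e-8)

    def test_component_bound_enforced(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValidationError, match="exceeds"):
            pls_fit(rng.normal(size=(5, 3)),
                    np.array([0, 1, 0, 1, 0.0]), 5)


class TestNestedLgocv:
    def _planted(self, seed, n_genes=200, n_signal=20, delta=0.8):
        rng = np.random.default_rng(seed)
        labels = np.array([True] * 40 + [False] * 20)
        y = rng.uniform(6, 10, n_genes)[:, None] + 0.5 * rng.standard_normal(
            (n_genes, 60))
        y[:n_signal, labels] += delta * 0.5
        return expr_from_log2(y), labels

    def test_seeded_bit_reproducibility(self):
        x, labels = self._planted(0)
        a = nested_lgocv(x, labels, sweep=(10, 40, 10), outer=6, inner=4, seed=3)
        b = nested_lgocv(x, labels, sweep=(10, 40, 10), outer=6, inner=4, seed=3)
        np.testing.assert_array_equal(a.outer_aucs, b.outer_aucs)
        assert a.selected_n == b.selected_n
        assert a.selected_genes == b.selected_genes

    def test_selection_bias_of_full_cohort_ranking(self):
        """Ranking on all samples leaks: null outer AUC lands above chance,
        while fold-internal ranking stays at chance level."""
        leaky, honest = [], []
        for s in range(12):
            rng = np.random.default_rng(500 + s)
            x = gaussian_matrix(rng, 200, 60)
            labels = np.array([True] * 40 + [False] * 20)
            for mode, sink in ((False, leaky), (True, honest)):
                rep = nested_lgocv(x, labels, sweep=(10, 30, 10), outer=20,
                                   inner=4, seed=s, rank_in_fold=mode)
                sink.append(rep.outer_aucs.mean())
        assert np.mean(leaky) > 0.5
        assert 0.45 <= np.mean(honest) <= 0.55
        assert np.mean(leaky) > np.mean(honest)

    def test_cv_zero_when_auc_saturates(self):
        x, labels = self._planted(1, delta=6.0)
        rep = nested_lgocv(x, labels, sweep=(10, 20, 10), outer=5, inner=3,
                           seed=0)
        assert rep.cv_of_auc[0] == 0.0  # sd of identical AUCs (all 1.0)
        assert rep.selected_n == 10  # tie resolved toward the smaller size

    def test_sweep_validation(self):
        x, labels = self._planted(2)
        with pytest.raises(ValidationError, match="exceeds"):
            nested_lgocv(x, labels, sweep=(10, 1000, 10), outer=2, inner=2)


class TestCompareModelSizes:
    def test_identical_vectors_p_half(self):
        a = np.full(50, 0.8)
        assert compare_model_sizes(a, a) == 0.5

    def test_strongly_shifted_alternative(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.7, 0.02, 100)
        b = rng.normal(0.8, 0.02, 100)
        assert compare_model_sizes(a, b) < 1e-6

    def test_one_sided_antisymmetry(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.7, 0.05, 60)
        b = rng.normal(0.72, 0.05, 60)
        assert compare_model_sizes(a, b) + compare_model_sizes(b, a) == \
            pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_model_sizes([0.5, 0.6], [0.7])


class TestRandomGenesetNull:
    def _cohorts(self, seed, planted=True):
        rng = np.random.default_rng(seed)
        n_genes = 300
        ytr = rng.uniform(6, 10, n_genes)[:, None] + 0.5 * rng.standard_normal(
            (n_genes, 60))
        yte = ytr[:, :0].copy()
        yte = rng.uniform(6, 10, n_genes)[:, None] + 0.5 * rng.standard_normal(
            (n_genes, 50))
        ltr = np.array([True] * 40 + [False] * 20)
        lte = np.array([True] * 30 + [False] * 20)
        if planted:
            ytr[:30, ltr] += 0.5
            yte[:30, lte] += 0.5
        genes = [f"g{i}" for i in range(n_genes)]
        return (expr_from_log2(ytr, genes=genes), ltr,
                expr_from_log2(yte, genes=genes), lte)

    def test_weak_observed_auc_lands_in_upper_tail(self):
        xtr, ltr, xte, lte = self._cohorts(0, planted=True)
        res = random_geneset_null(xtr, ltr, xte, lte, observed_auc=0.5,
                                  k=30, n_draws=50, seed=1)
        assert res["p_value"] > 0.5

    def test_planted_signature_beats_random_draws(self):
        wins = 0
        for s in range(10):
            xtr, ltr, xte, lte = self._cohorts(100 + s, planted=True)
            sig = [f"g{i}" for i in range(30)]
            model = pls_fit(xtr.subset_features(sig).log2().T,
                            ltr.astype(float), 3, feature_ids=sig)
            obs = evaluate(pls_predict(model, xte.subset_features(sig).log2().T),
                           lte).auc
            res = random_geneset_null(xtr, ltr, xte, lte, observed_auc=obs,
                                      k=30, n_draws=200, seed=s)
            wins += res["p_value"] <= 0.005
        assert wins >= 9

    def test_k_exceeding_gene_count_rejected(self):
        xtr, ltr, xte, lte = self._cohorts(1)
        with pytest.raises(ValidationError):
            random_geneset_null(xtr, ltr, xte, lte, observed_auc=0.5, k=10_000)


class TestEvaluate:
    def test_majority_class_predictor_balanced_accuracy_half(self):
        scores = np.ones(100)  # calls every sample a case
        labels = np.array([True] * 80 + [False] * 20)
        perf = evaluate(scores, labels)
        assert perf.balanced_accuracy == 0.5
        assert perf.accuracy == 0.8  # plain accuracy inflated by imbalance

    def test_perfect_scores(self):
        labels = np.array([True] * 10 + [False] * 10)
        scores = labels.astype(float)
        perf = evaluate(scores, labels)
        for v in (perf.auc, perf.accuracy, perf.sensitivity, perf.specificity,
                  perf.ppv, perf.npv, perf.balanced_accuracy):
            assert v == 1.0

    def test_balanced_accuracy_from_published_sensitivity_specificity(self):
        # sens 0.900 and spec 0.438 average to 0.669
        n_case, n_ctrl = 10, 16
        labels = np.array([True] * n_case + [False] * n_ctrl)
        scores = np.concatenate([
            np.r_[np.full(9, 0.9), [0.1]],              # 9/10 cases called
            np.r_[np.full(7, 0.1), np.full(9, 0.9)]])   # 7/16 controls correct
        perf = evaluate(scores, labels)
        assert perf.sensitivity == pytest.approx(0.900, abs=1e-3)
        assert perf.specificity == pytest.approx(0.4375, abs=1e-4)
        assert perf.balanced_accuracy == pytest.approx(0.669, abs=2e-3)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[0], labels[1] = True, False
        a = evaluate(scores, labels).auc
        b = evaluate(np.exp(scores), labels, threshold=1.0).auc
        assert a == pytest.approx(b)

    def test_delong_interval_brackets_auc(self):
        rng = np.random.default_rng(10)
        labels = np.array([True] * 40 + [False] * 40)
        scores = rng.normal(size=80) + labels * 1.0
        perf = evaluate(scores, labels)
        lo, hi = perf.auc_ci
        assert lo <= perf.auc <= hi
        assert hi - lo < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([0.1, 0.9], [True, True])


class TestLdaAndClustering:
    def test_lda_matches_direct_matrix_oracle(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(6, 10, (5, 30)) + 0.2 * rng.standard_normal((5, 30))
        labels = np.array([True] * 15 + [False] * 15)
        y[:, labels] += 0.5
        x = expr_from_log2(y)
        scores = fisher_lda_score(x, labels)
        yl = x.log2().T
        mu1, mu0 = yl[labels].mean(0), yl[~labels].mean(0)
        d1, d0 = yl[labels] - mu1, yl[~labels] - mu0
        w = np.linalg.solve(d1.T @ d1 + d0.T @ d0, mu1 - mu0)
        expected = yl @ w
        if expected[labels].mean() < expected[~labels].mean():
            expected = -expected
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-9)

    def test_lda_separates_well_separated_classes(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(6, 10, (20, 60)) + 0.3 * rng.standard_normal((20, 60))
        labels = np.array([True] * 30 + [False] * 30)
        y[:5, labels] += 2.0
        scores = fisher_lda_score(expr_from_log2(y), labels).to_numpy()
        within = max(scores[labels].std(), scores[~labels].std())
        assert scores[labels].mean() > scores[~labels].mean() + 2 * within

    def test_duplicated_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(13)
        y = rng.uniform(5, 9, (30, 8))
        y[:, 7] = y[:, 6]
        res = hcluster_heatmap(expr_from_log2(y))
        z = res["linkage"]
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {6, 7}

    def test_two_planted_classes_recovered(self):
        rng = np.random.default_rng(14)
        y = rng.uniform(6, 10, (40, 50)) + 0.3 * rng.standard_normal((40, 50))
        labels = np.array([True] * 25 + [False] * 25)
        y[:25, labels] += 3.0  # clearly separable class structure
        res = hcluster_heatmap(expr_from_log2(y), n_clusters=2)
        assign = np.array([res["clusters"][f"s{i}"] for i in range(50)])
        agree = max((assign[labels] == 1).mean() + (assign[~labels] == 2).mean(),
                    (assign[labels] == 2).mean() + (assign[~labels] == 1).mean()) / 2
        assert agree >= 0.9

    def test_average_linkage_heights_monotone(self):
        rng = np.random.default_rng(15)
        y = rng.uniform(5, 9, (25, 20))
        z = hcluster_heatmap(expr_from_log2(y))["linkage"]
        assert (np.diff(z[:, 2]) >= -1e-12).all()
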