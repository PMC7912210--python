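import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve

from methdx import (
    FeatureView,
    build_views,
    incremental_selection,
    loo_scores,
    rank_importance,
    roc_auc,
    scale_importance,
)

from conftest import two_group_labels


def make_view(matrix, genes, samples, kind="expression"):
    return FeatureView(kind, pd.DataFrame(matrix, index=genes, columns=samples))


@pytest.fixture()
def separable_view(rng):
    """One perfectly separating feature among pure-noise features."""
    labels = two_group_labels(10, 10)
    X = rng.normal(size=(6, 20))
    X[0] = np.where(labels.to_numpy() == "case", 2.0, -2.0)
    genes = [f"g{i}" for i in range(6)]
    return make_view(X, genes, labels.index), labels


class TestScaleImportance:
    def test_closed_form(self):
        np.testing.assert_allclose(scale_importance([2.0, 4.0, 6.0]), [0.0, 50.0, 100.0])

    def test_endpoints_always_0_and_100(self, rng):
        raw = rng.uniform(0, 5, size=30)
        scaled = scale_importance(raw)
        assert scaled.max() == pytest.approx(100.0)
        assert scaled.min() == pytest.approx(0.0)
        assert scaled[np.argmax(raw)] == pytest.approx(100.0)
        assert scaled[np.argmin(raw)] == pytest.approx(0.0)

    def test_singleton_degenerates_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = scale_importance([7.0])
        np.testing.assert_allclose(out, [0.0])

    def test_all_equal_degenerates_to_zeros(self):
        with pytest.warns(UserWarning):
            out = scale_importance([3.0, 3.0, 3.0])
        np.testing.assert_allclose(out, [0.0, 0.0, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scale_importance([])

    def test_series_keeps_index(self):
        s = pd.Series([1.0, 3.0], index=["a", "b"])
        out = scale_importance(s)
        assert list(out.index) == ["a", "b"]


class TestRankImportance:
    def test_separating_feature_ranks_first(self, separable_view):
        view, labels = separable_view
        ranking = rank_importance(view, labels, seed=0, n_trees=100)
        assert ranking.index[0] == "g0"

    def test_constant_feature_zero_importance(self, rng):
        labels = two_group_labels(8, 8)
        X = rng.normal(size=(3, 16))
        X[2] = 5.0  # constant
        view = make_view(X, ["a", "b", "const"], labels.index)
        ranking = rank_importance(view, labels, seed=0, n_trees=50)
        assert ranking["const"] == 0.0

    def test_deterministic_given_seed(self, separable_view):
        view, labels = separable_view
        r1 = rank_importance(view, labels, seed=3, n_trees=50)
        r2 = rank_importance(view, labels, seed=3, n_trees=50)
        pd.testing.assert_series_equal(r1, r2)

    def test_single_class_rejected(self, rng):
        labels = pd.Series(["case"] * 6, index=[f"s{i}" for i in range(6)])
        view = make_view(rng.normal(size=(2, 6)), ["a", "b"], labels.index)
        with pytest.raises(ValueError):
            rank_importance(view, labels, seed=0, n_trees=10)

    def test_permutation_importance_variant(self, separable_view):
        view, labels = separable_view
        ranking = rank_importance(view, labels, seed=0, n_trees=100,
                                  method="permutation")
        assert ranking.index[0] == "g0"


class TestLooScores:
    def test_one_score_per_sample(self, rng):
        labels = two_group_labels(2, 2)
        view = make_view(rng.normal(size=(2, 4)), ["a", "b"], labels.index)
        scores = loo_scores(view, labels, seed=0, n_trees=10)
        assert len(scores) == 4
        assert list(scores.index) == list(labels.index)

    def test_perfect_separability_gives_auc_one(self):
        labels = two_group_labels(5, 5)
        X = np.where(labels.to_numpy() == "case", 1.0, 0.0)[None, :]
        X = np.vstack([X, X])
        view = make_view(X, ["a", "b"], labels.index)
        scores = loo_scores(view, labels, seed=0, n_trees=50)
        auc, _ = roc_auc(scores, labels)
        assert auc == 1.0

    def test_needs_three_samples(self, rng):
        labels = two_group_labels(1, 1)
        view = make_view(rng.normal(size=(1, 2)), ["a"], labels.index)
        with pytest.raises(ValueError):
            loo_scores(view, labels, seed=0, n_trees=10)

    def test_permutation_null_centred_on_half(self, rng):
        """Over label permutations the LOO AUC distribution centres on 0.5
        (no signal leaks through the cross-validation)."""
        n = 16
        base = two_group_labels(8, 8)
        view = make_view(rng.normal(size=(4, n)), list("abcd"), base.index)
        aucs = []
        for rep in range(20):
            perm = rng.permutation(n)
            labels = pd.Series(base.to_numpy()[perm], index=base.index)
            scores = loo_scores(view, labels, seed=rep, n_trees=30)
            aucs.append(roc_auc(scores, labels)[0])
        aucs = np.array(aucs)
        assert abs(aucs.mean() - 0.5) < 3 * aucs.std(ddof=1) / np.sqrt(len(aucs))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = two_group_labels(2, 2)
        scores = pd.Series([0.9, 0.8, 0.1, 0.2], index=labels.index)
        auc, p = roc_auc(scores, labels)
        assert auc == 1.0

    def test_tie_counting_worked_example(self):
        labels = pd.Series(["control", "control", "case", "case"],
                           index=list("wxyz"))
        scores = pd.Series([0.2, 0.4, 0.4, 0.8], index=list("wxyz"))
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx((1 + 0.5 + 2) / 4)

    def test_label_swap_symmetry(self, rng):
        labels = two_group_labels(6, 4)
        scores = pd.Series(rng.normal(size=10), index=labels.index)
        auc, _ = roc_auc(scores, labels)
        swapped = labels.map({"case": "control", "control": "case"})
        auc_swapped, _ = roc_auc(scores, swapped)
        assert auc_swapped == pytest.approx(1.0 - auc, abs=1e-12)

    def test_matches_all_pairs_and_trapezoid(self, rng):
        """AUC equals both the all-pairs counting oracle and trapezoidal
        integration of the empirical ROC curve to 1e-10."""
        for _ in range(30):
            n1, n0 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            labels = two_group_labels(n1, n0)
            scores = pd.Series(
                rng.choice(np.round(rng.normal(size=6), 2), size=n1 + n0),
                index=labels.index,
            )  # coarse grid forces ties
            auc, _ = roc_auc(scores, labels)
            case = scores[labels == "case"].to_numpy()
            ctrl = scores[labels == "control"].to_numpy()
            pairs = sum(
                1.0 if c > d else 0.5 if c == d else 0.0
                for c in case for d in ctrl
            ) / (n1 * n0)
            assert auc == pytest.approx(pairs, abs=1e-10)
            fpr, tpr, _ = roc_curve((labels == "case").astype(int), scores)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    def test_single_class_rejected(self):
        labels = pd.Series(["case", "case"], index=["a", "b"])
        with pytest.raises(ValueError):
            roc_auc(pd.Series([0.1, 0.2], index=["a", "b"]), labels)


class TestIncrementalSelection:
    def test_single_gene_best_k_is_one(self, rng):
        labels = two_group_labels(4, 4)
        view = make_view(rng.normal(size=(1, 8)), ["a"], labels.index)
        report = incremental_selection(view, ["a"], labels, seed=0, n_trees=20)
        assert report.best_k == 1
        assert set(report.auc_by_k) == {1}

    def test_best_k_is_argmax_with_smallest_tie(self, separable_view):
        view, labels = separable_view
        ranking = rank_importance(view, labels, seed=0, n_trees=50)
        report = incremental_selection(view, list(ranking.index), labels,
                                       seed=0, n_trees=50,
                                       raw_importance=ranking)
        best_auc = report.auc_by_k[report.best_k]
        assert all(best_auc >= v for v in report.auc_by_k.values())
        ties = [k for k, v in report.auc_by_k.items() if v == best_auc]
        assert report.best_k == min(ties)

    def test_informative_first_gene_dominates_curve(self, separable_view):
        view, labels = separable_view
        ranking = rank_importance(view, labels, seed=0, n_trees=100)
        assert ranking.index[0] == "g0"
        report = incremental_selection(view, list(ranking.index), labels,
                                       seed=0, n_trees=100,
                                       raw_importance=ranking)
        G = len(ranking)
        assert report.auc_by_k[1] >= report.auc_by_k[G] - 0.1
        assert report.best_k <= 3
        assert report.ranked["scaled_importance"].iloc[0] == pytest.approx(100.0)
        assert report.ranked["scaled_importance"].iloc[-1] == pytest.approx(0.0)

    def test_empty_ranking_rejected(self, separable_view):
        view, labels = separable_view
        with pytest.raises(ValueError):
            incremental_selection(view, [], labels, seed=0)

    def test_nested_protocol_runs(self, rng):
        labels = two_group_labels(5, 5)
        X = rng.normal(size=(3, 10))
        X[0] += np.where(labels.to_numpy() == "case", 2.0, -2.0)
        view = make_view(X, list("abc"), labels.index)
        report = incremental_selection(view, list("abc"), labels, seed=0,
                                       n_trees=20, nested=True)
        assert set(report.auc_by_k) == {1, 2, 3}
        assert len(report.loo_scores) == 10


class TestFeatureViews:
    def test_beta_view_range_check(self):
        bad = pd.DataFrame([[1.2]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            FeatureView("beta_all_regions", bad)

    def test_build_views_dominant_mean(self, rng):
        samples = ["s1", "s2"]
        expr = pd.DataFrame(rng.normal(size=(2, 2)), index=["g1", "g2"],
                            columns=samples)
        gene_beta = pd.DataFrame([[0.3, 0.4], [0.2, 0.2]], index=["g1", "g2"],
                                 columns=samples)
        region_beta = pd.DataFrame(
            [[0.2, 0.3], [0.6, 0.5], [0.1, 0.2]],
            index=pd.MultiIndex.from_tuples(
                [("g1", "Body"), ("g1", "TSS200"), ("g2", "Body")],
                names=["gene", "region"]),
            columns=samples,
        )
        dominant = {"g1": ("Body", "TSS200"), "g2": ("Body",)}
        views = build_views(expr, gene_beta, region_beta, dominant, ["g1", "g2"])
        dom = views["beta_dominant_regions"].matrix
        assert dom.loc["g1", "s1"] == pytest.approx(0.4)  # mean of 0.2, 0.6
        assert dom.loc["g2", "s2"] == pytest.approx(0.2)

    def test_gene_without_dominant_records_dropped(self, rng):
        samples = ["s1"]
        expr = pd.DataFrame(index=pd.Index([], name="gene"), columns=samples)
        gene_beta = pd.DataFrame([[0.3]], index=["g1"], columns=samples)
        region_beta = pd.DataFrame(
            [[0.2]],
            index=pd.MultiIndex.from_tuples([("g1", "Body")],
                                            names=["gene", "region"]),
            columns=samples,
        )
        views = build_views(expr, gene_beta, region_beta, {}, ["g1"])
        assert views["beta_dominant_regions"].matrix.empty
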