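import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoblocks.shape_stats import (
    SingularCovarianceError,
    anova_tukey,
    factorial_manova,
    join_views,
    pairwise_manova,
    shape_pca,
    wilks_manova,
)


class TestShapePca:
    def test_collinear_data_single_component(self, rng):
        direction = rng.normal(size=6)
        x = np.outer(rng.normal(size=10), direction)
        space = shape_pca(x)
        assert space.d == 1
        assert space.variance_explained[0] == pytest.approx(1.0)

    def test_reconstruction_with_all_components(self, rng):
        x = rng.normal(size=(12, 5))
        space = shape_pca(x)
        np.testing.assert_allclose(space.reconstruct(), x, atol=1e-10)

    def test_eigenvalues_match_dense_eigensolver(self, rng):
        x = rng.normal(size=(10, 6))
        space = shape_pca(x)
        cov = np.cov(x, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(space.eigenvalues,
                                   expected[:space.d], atol=1e-10)

    def test_total_variance_conserved(self, rng):
        x = rng.normal(size=(15, 8))
        space = shape_pca(x)
        total = np.var(x, axis=0, ddof=1).sum()
        assert space.eigenvalues.sum() == pytest.approx(total, abs=1e-10)

    def test_scores_centred_and_vectors_orthonormal(self, rng):
        x = rng.normal(size=(20, 7))
        space = shape_pca(x)
        np.testing.assert_allclose(space.scores.mean(axis=0), 0,
                                   atol=1e-10)
        np.testing.assert_allclose(
            space.eigenvectors.T @ space.eigenvectors,
            np.eye(space.d), atol=1e-10)

    def test_rotation_invariant_spectrum(self, rng):
        x = rng.normal(size=(15, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        np.testing.assert_allclose(shape_pca(x @ q).eigenvalues,
                                   shape_pca(x).eigenvalues, atol=1e-9)

    def test_deterministic_sign_convention(self, rng):
        x = rng.normal(size=(10, 4))
        space = shape_pca(x)
        for j in range(space.d):
            col = space.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_specimens_rejected(self, rng):
        with pytest.raises(ValueError):
            shape_pca(rng.normal(size=(2, 4)))


class TestJoinViews:
    def test_self_join_doubles_eigenvalues(self, rng):
        x = rng.normal(size=(12, 5))
        space = shape_pca(x, ids=tuple("abcdefghijkl"))
        joined = join_views([space, space])
        np.testing.assert_allclose(joined.eigenvalues,
                                   2 * space.eigenvalues, atol=1e-9)

    def test_total_variance_is_sum_of_inputs(self, rng):
        ids = tuple(f"s{i}" for i in range(10))
        spaces = [shape_pca(rng.normal(size=(10, d)), ids=ids)
                  for d in (4, 6, 3)]
        joined = join_views(spaces)
        assert joined.source_view == "integrated"
        assert joined.eigenvalues.sum() == pytest.approx(
            sum(sp.eigenvalues.sum() for sp in spaces), rel=1e-10)
        assert joined.d <= 9    # bounded by n - 1

    def test_mismatched_specimens_rejected(self, rng):
        a = shape_pca(rng.normal(size=(10, 4)),
                      ids=tuple(f"s{i}" for i in range(10)))
        b = shape_pca(rng.normal(size=(10, 4)),
                      ids=tuple(f"t{i}" for i in range(10)))
        with pytest.raises(ValueError, match="differ"):
            join_views([a, b])


class TestWilksManova:
    def test_identical_group_means_gives_lambda_one(self):
        base = np.array([[1.0, 2.0], [3.0, 0.0], [0.0, 1.0]])
        x = np.vstack([base, base])     # both groups share the same points
        res = wilks_manova(x, ["a"] * 3 + ["b"] * 3)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_univariate_case_matches_anova_closed_form(self, rng):
        x = rng.normal(size=40)
        labels = np.repeat(list("abcd"), 10)
        x[labels == "c"] += 1.0
        res = wilks_manova(x, labels)
        F, p = stats.f_oneway(*[x[labels == g] for g in "abcd"])
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        lam = 1 / (1 + res.F * res.df1 / res.df2)
        assert res.wilks_lambda == pytest.approx(lam, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        x = rng.normal(size=(45, 3))
        labels = rng.choice(list("abc"), size=45)
        x[labels == "b"] += 0.8
        res = wilks_manova(x, labels)
        df = pd.DataFrame(x, columns=["y1", "y2", "y3"])
        df["g"] = labels
        table = MANOVA.from_formula(
            "y1 + y2 + y3 ~ g", data=df).mv_test().results["g"]["stat"]
        row = table.loc["Wilks' lambda"]
        assert res.wilks_lambda == pytest.approx(row["Value"], abs=1e-10)
        assert res.F == pytest.approx(row["F Value"], rel=1e-9)
        assert res.p == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_invariant_under_invertible_linear_map(self, rng):
        x = rng.normal(size=(30, 4))
        labels = np.repeat(list("abc"), 10)
        x[labels == "a"] += 0.5
        a = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        res1 = wilks_manova(x, labels)
        res2 = wilks_manova(x @ a, labels)
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda,
                                                  rel=1e-9)

    def test_type_i_error_calibrated(self):
        # null rejection rate near alpha (reduced replicate count here;
        # the full-scale calibration runs in the acceptance suite)
        rejections = 0
        n_sim = 400
        labels = np.repeat(list("abcd"), [25, 17, 18, 29])
        rng = np.random.default_rng(99)
        for _ in range(n_sim):
            x = rng.normal(size=(89, 5))
            if wilks_manova(x, labels).p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_singular_within_sscp_raises(self):
        x = np.zeros((8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        with pytest.raises(SingularCovarianceError, match="PC"):
            wilks_manova(x, labels)


class TestPairwiseManova:
    def test_four_groups_six_comparisons(self, rng):
        x = rng.normal(size=(40, 3))
        labels = np.repeat(list("abcd"), 10)
        table = pairwise_manova(x, labels, alpha=0.05)
        assert len(table) == 6
        assert table.attrs["bonferroni_threshold"] == pytest.approx(
            0.05 / 6)

    def test_two_groups_reduce_to_single_test(self, rng):
        x = rng.normal(size=(20, 3))
        labels = np.repeat(["a", "b"], 10)
        table = pairwise_manova(x, labels, auto_reduce=False)
        res = wilks_manova(x, labels)
        assert len(table) == 1
        assert table.loc[0, "wilks_lambda"] == pytest.approx(
            res.wilks_lambda)
        assert table.loc[0, "p"] == pytest.approx(res.p)

    def test_familywise_error_controlled(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(list("abcd"), 8)
        any_flag = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=(32, 2))
            if pairwise_manova(x, labels).significant.any():
                any_flag += 1
        assert any_flag / n_sim <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / n_sim)

    def test_small_groups_auto_reduce_dimension(self, rng):
        x = rng.normal(size=(13, 10))
        labels = ["a"] * 3 + ["b"] * 4 + ["c"] * 6
        table = pairwise_manova(x, labels)
        row = table[(table.group_a == "a") & (table.group_b == "b")]
        assert int(row.d_used.iloc[0]) <= 4


class TestFactorialManova:
    def test_constant_factor_degenerates_to_oneway(self, rng):
        x = rng.normal(size=(24, 3))
        a = np.repeat(["x", "y", "z"], 8)
        b = np.repeat("only", 24)
        results = factorial_manova(x, a, b, names=("A", "B"))
        assert len(results) == 1
        ref = wilks_manova(x, a, term="A")
        assert results[0].wilks_lambda == pytest.approx(ref.wilks_lambda)
        assert results[0].F == pytest.approx(ref.F)

    def test_additive_truth_interaction_near_null(self):
        # balanced 2x2 with purely additive effects: the interaction term
        # rejects at ~alpha
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 300
        a = np.repeat(["m", "f"], 40)
        b = np.tile(np.repeat(["p", "q"], 20), 2)
        for _ in range(n_sim):
            x = rng.normal(size=(80, 2))
            x[a == "m"] += [1.0, 0.0]
            x[b == "p"] += [0.0, 1.0]
            inter = factorial_manova(x, a, b)[2]
            assert inter.term == "A:B"
            if inter.p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 3 * np.sqrt(
            0.05 * 0.95 / n_sim)

    def test_empty_cell_rejected(self, rng):
        x = rng.normal(size=(12, 2))
        a = np.repeat(["u", "v"], 6)
        b = np.array(["p"] * 6 + ["q"] * 6)   # u only with p, v only q
        with pytest.raises(ValueError, match="empty"):
            factorial_manova(x, a, b)

    def test_unbalanced_study_design_runs(self, paper_size_dataset):
        dataset, _ = paper_size_dataset
        recs = sorted(dataset.records.values(),
                      key=lambda r: r.specimen_id)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(89, 4))
        sex = [r.sex for r in recs]
        block = [r.block for r in recs]
        results = factorial_manova(x, sex, block, names=("sex", "block"))
        assert [r.term for r in results] == ["sex", "block", "sex:block"]
        for r in results:
            assert 0 <= r.p <= 1


class TestAnovaTukey:
    def test_two_groups_f_equals_squared_t(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15) + 0.5
        F, p, _ = anova_tukey(np.concatenate([a, b]),
                              ["a"] * 12 + ["b"] * 15)
        t, tp = stats.ttest_ind(a, b)
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(tp, abs=1e-12)

    def test_tukey_matches_scipy_and_flags(self, rng):
        values = np.concatenate([rng.normal(size=10),
                                 rng.normal(size=14) + 3.0,
                                 rng.normal(size=8)])
        labels = ["a"] * 10 + ["b"] * 14 + ["c"] * 8
        _, _, table = anova_tukey(values, labels)
        assert len(table) == 3
        ab = table[(table.group_a == "a") & (table.group_b == "b")]
        assert bool(ab.significant.iloc[0])

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="2 members"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])
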