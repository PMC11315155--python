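"""Preprocessing, ordination and latent-variable models against
independent oracles (explicit enumeration, eigen-solvers, scikit-learn and
scikit-bio)."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import aromakit as ak
from aromakit import chemometrics as chem
from aromakit.errors import (ConfigurationError, ModelError,
                             StratificationError, ValidationError)


@pytest.fixture()
def two_class():
    rng = np.random.default_rng(42)
    x = pd.DataFrame(rng.normal(size=(8, 5)),
                     columns=[f"v{i}" for i in range(5)])
    y = np.array(["a"] * 4 + ["b"] * 4)
    return x, y


class TestImputeMissing:
    def test_fifth_of_minimum_rule(self):
        frame = pd.DataFrame({"c": [10.0, np.nan, 20.0]})
        out, dropped = chem.impute_missing(frame)
        assert out["c"].tolist() == [10.0, 2.0, 20.0]
        assert dropped == []

    def test_no_missing_is_identity(self):
        frame = pd.DataFrame({"c": [1.0, 2.0]})
        out, _ = chem.impute_missing(frame)
        pd.testing.assert_frame_equal(out, frame)

    def test_all_missing_column_dropped_and_reported(self):
        frame = pd.DataFrame({"c": [1.0, 2.0], "gone": [np.nan, np.nan]})
        out, dropped = chem.impute_missing(frame)
        assert dropped == ["gone"]
        assert list(out.columns) == ["c"]


class TestNormalizeToReference:
    def test_scaled_sample_collapses_onto_reference(self):
        ref = pd.Series([1.0, 2.0, 4.0], name="ref")
        frame = pd.DataFrame([ref, 2 * ref], index=["ref", "double"])
        out = chem.normalize_to_reference(frame, "ref")
        np.testing.assert_allclose(out.loc["double"], out.loc["ref"])

    def test_reference_row_unchanged(self):
        frame = pd.DataFrame(np.arange(1.0, 13.0).reshape(3, 4),
                             index=["r0", "r1", "r2"])
        out = chem.normalize_to_reference(frame, "r1")
        np.testing.assert_allclose(out.loc["r1"], frame.loc["r1"])

    def test_matches_explicit_median_quotient(self, rng):
        frame = pd.DataFrame(rng.uniform(0.5, 5.0, size=(5, 4)),
                             index=list("abcde"))
        out = chem.normalize_to_reference(frame, "c")
        for row in frame.index:
            quotients = sorted(frame.loc[row] / frame.loc["c"])
            median = (quotients[1] + quotients[2]) / 2  # 4 values
            np.testing.assert_allclose(out.loc[row], frame.loc[row] / median)

    def test_unknown_reference_raises(self):
        frame = pd.DataFrame({"c": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            chem.normalize_to_reference(frame, "nope")


class TestParetoScale:
    def test_closed_form_two_values(self):
        frame = pd.DataFrame({"c": [1.0, 3.0]})
        out = chem.pareto_scale(frame)
        expected = (np.array([1.0, 3.0]) - 2.0) / np.sqrt(np.sqrt(2.0))
        np.testing.assert_allclose(out["c"], expected)
        assert out["c"].iloc[1] == pytest.approx(0.8409, abs=1e-4)

    def test_constant_column_zeroed_and_flagged(self):
        frame = pd.DataFrame({"c": [1.0, 3.0], "k": [5.0, 5.0]})
        out = chem.pareto_scale(frame)
        assert (out["k"] == 0).all()
        assert out.attrs["constant_columns"] == ["k"]

    def test_columns_centered(self, rng):
        frame = pd.DataFrame(rng.normal(size=(6, 4)))
        out = chem.pareto_scale(frame)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        frame = pd.DataFrame([[1.0, 2.0, 5.0, 9.0],
                              [1.0, 4.0, 25.0, 81.0]], index=["s1", "s2"])
        out = chem.spearman_matrix(frame)
        assert out.at["s1", "s2"] == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0],
                              [9.0, 6.0, 4.0, 1.0]], index=["s1", "s2"])
        assert chem.spearman_matrix(frame).at["s1", "s2"] == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self, rng):
        frame = pd.DataFrame(rng.integers(0, 4, size=(4, 10)).astype(float))
        out = chem.spearman_matrix(frame)
        ranks = frame.T.rank(method="average")  # average ranks across ties
        expected = np.corrcoef(ranks.T)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)


class TestPcoa:
    def test_two_points_in_three_samples_geometry(self):
        frame = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]],
                             index=["a", "b", "c"])
        out = chem.pcoa(frame, metric="euclidean")
        d = squareform(pdist(out.coordinates, "euclidean"))
        assert d[0, 1] == pytest.approx(5.0, abs=1e-10)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_isometry(self, rng):
        frame = pd.DataFrame(rng.normal(size=(7, 2)))
        out = chem.pcoa(frame, metric="euclidean")
        original = pdist(frame, "euclidean")
        embedded = pdist(out.coordinates, "euclidean")
        np.testing.assert_allclose(embedded, original, atol=1e-10)

    def test_braycurtis_matches_dense_eigensolver(self, rng):
        frame = pd.DataFrame(np.abs(rng.normal(size=(6, 4))) + 0.1)
        out = chem.pcoa(frame, metric="braycurtis")
        d2 = squareform(pdist(frame, "braycurtis")) ** 2
        j = np.eye(6) - np.ones((6, 6)) / 6
        eigval = np.linalg.eigvalsh(-0.5 * j @ d2 @ j)[::-1]
        np.testing.assert_allclose(out.eigenvalues,
                                   eigval[:len(out.eigenvalues)], atol=1e-12)
        assert len(out.negative_eigenvalues) > 0  # Bray-Curtis is non-Euclidean

    def test_matches_scikit_bio(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        frame = pd.DataFrame(np.abs(rng.normal(size=(6, 4))) + 0.1)
        mine = chem.pcoa(frame, metric="braycurtis")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_ordination.pcoa(squareform(pdist(frame, "braycurtis")))
        k = len(mine.eigenvalues)
        np.testing.assert_allclose(mine.eigenvalues, ref.eigvals.values[:k],
                                   atol=1e-10)
        for i in range(k):
            a = mine.coordinates.to_numpy()[:, i]
            b = ref.samples.to_numpy()[:, i]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_equals_pca_scores_on_euclidean(self, rng):
        frame = pd.DataFrame(rng.normal(size=(6, 4)))
        out = chem.pcoa(frame, metric="euclidean")
        centered = frame - frame.mean(axis=0)
        u, s, _ = np.linalg.svd(centered.to_numpy(), full_matrices=False)
        scores = u * s
        for i in range(out.coordinates.shape[1]):
            a = out.coordinates.to_numpy()[:, i]
            assert min(np.abs(a - scores[:, i]).max(),
                       np.abs(a + scores[:, i]).max()) < 1e-8

    def test_unknown_metric_raises(self, rng):
        frame = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ConfigurationError):
            chem.pcoa(frame, metric="not-a-metric")


class TestPlsda:
    def test_single_informative_variable_dominates_weights(self):
        x = pd.DataFrame(0.0, index=range(6), columns=["v0", "v1", "v2"])
        x["v1"] = [1.0, 1.0, 1.0, -1.0, -1.0, -1.0]
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = chem.fit_plsda(x, y, n_components=1)
        np.testing.assert_allclose(np.abs(model.w[:, 0]), [0.0, 1.0, 0.0],
                                   atol=1e-12)

    def test_rank_one_x_fully_deflated(self, rng):
        v = rng.normal(size=4)
        t = np.array([1.0, 2.0, -1.0, -2.0, 0.5, -0.5])
        x = pd.DataFrame(np.outer(t, v))
        y = np.array(["a", "a", "b", "b", "a", "b"])
        model = chem.fit_plsda(x, y, n_components=1)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        residual = xc - np.outer(model.t[:, 0], model.p[:, 0])
        np.testing.assert_allclose(residual, 0.0, atol=1e-10)

    def test_component_one_matches_eigen_oracle(self, two_class):
        """w1 is the dominant eigenvector of Xc' Yc Yc' Xc (power iteration)."""
        x, y = two_class
        model = chem.fit_plsda(x, y, n_components=1)
        hot = np.column_stack([(y == c).astype(float) for c in ["a", "b"]])
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        yc = hot - hot.mean(axis=0)
        m = xc.T @ yc @ yc.T @ xc
        v = np.ones(m.shape[0])
        for _ in range(10000):
            v = m @ v
            v /= np.linalg.norm(v)
        assert min(np.linalg.norm(model.w[:, 0] - v),
                   np.linalg.norm(model.w[:, 0] + v)) < 1e-6

    def test_component_one_matches_sklearn(self, two_class):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        x, y = two_class
        model = chem.fit_plsda(x, y, n_components=2)
        hot = np.column_stack([(y == c).astype(float) for c in ["a", "b"]])
        ref = sklearn_pls.PLSRegression(n_components=2, scale=False).fit(
            x.to_numpy() - x.to_numpy().mean(0), hot - hot.mean(0))
        for a in range(2):
            w_ref = ref.x_weights_[:, a] / np.linalg.norm(ref.x_weights_[:, a])
            assert min(np.linalg.norm(model.w[:, a] - w_ref),
                       np.linalg.norm(model.w[:, a] + w_ref)) < 1e-8

    def test_scores_mutually_orthogonal(self, two_class):
        x, y = two_class
        model = chem.fit_plsda(x, y, n_components=3)
        t = model.t
        for a in range(3):
            for b in range(a + 1, 3):
                bound = 1e-8 * np.linalg.norm(t[:, a]) * np.linalg.norm(t[:, b])
                assert abs(t[:, a] @ t[:, b]) < bound

    def test_single_class_raises(self, two_class):
        x, _ = two_class
        with pytest.raises(ModelError):
            chem.fit_plsda(x, np.array(["a"] * 8), n_components=1)


class TestVip:
    def test_uniform_weights_give_unit_vips(self):
        x = pd.DataFrame(np.outer([1.0, 1, -1, -1],
                                  [1.0, 1.0, 1.0, 1.0]),
                         columns=list("abcd"))
        y = np.array(["u", "u", "v", "v"])
        vip = chem.compute_vip(chem.fit_plsda(x, y, n_components=1))
        np.testing.assert_allclose(vip, 1.0, atol=1e-10)

    def test_concentrated_weight_is_sqrt_p(self):
        x = pd.DataFrame(0.0, index=range(4), columns=list("abcd"))
        x["b"] = [1.0, 1.0, -1.0, -1.0]
        y = np.array(["u", "u", "v", "v"])
        vip = chem.compute_vip(chem.fit_plsda(x, y, n_components=1))
        assert vip["b"] == pytest.approx(2.0)     # sqrt(4)
        np.testing.assert_allclose(vip[["a", "c", "d"]], 0.0, atol=1e-12)

    def test_two_component_model_matches_formula_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 4)))
        y = np.array(["u", "u", "u", "v", "v", "v"])
        model = chem.fit_plsda(x, y, n_components=2)
        vip = chem.compute_vip(model)
        p = 4
        for j in range(p):
            acc = sum(model.ss[a] * (model.w[j, a]
                                     / np.linalg.norm(model.w[:, a])) ** 2
                      for a in range(2))
            expected = np.sqrt(p * acc / model.ss.sum())
            assert vip.iloc[j] == pytest.approx(expected, rel=1e-12)

    def test_sum_of_squares_is_number_of_variables(self, two_class, rng):
        x, y = two_class
        for spec in [chem.ModelSpec("plsda", 2),
                     chem.ModelSpec("plsda", 3),
                     chem.ModelSpec("oplsda", n_orthogonal=1)]:
            vip = chem.compute_vip(spec.fit(x, y))
            assert (vip ** 2).sum() == pytest.approx(len(x.columns))

    def test_select_discriminants_strict_cutoff(self):
        vip = pd.Series({"a": 1.0, "b": 2.0, "c": 0.0})
        assert list(chem.select_discriminants(vip).index) == ["b"]
        assert chem.select_discriminants(pd.Series({"a": 1.0})).empty


class TestOplsda:
    def test_zero_orthogonal_reduces_to_pls1(self, two_class):
        x, y = two_class
        opls = chem.fit_oplsda(x, y, n_orthogonal=0)
        pls = chem.fit_plsda(x, y, n_components=1)
        assert min(np.linalg.norm(opls.w[:, 0] - pls.w[:, 0]),
                   np.linalg.norm(opls.w[:, 0] + pls.w[:, 0])) < 1e-10

    def test_orthogonal_component_captures_structured_noise(self):
        """Variable 1 mixes class signal with class-orthogonal structure,
        variable 2 carries the structure alone. The orthogonal component
        removes the structure, leaving predictive scores uncorrelated
        with it."""
        y = np.array(["a"] * 4 + ["b"] * 4)
        class_dir = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        struct = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        x = pd.DataFrame({"v1": class_dir + struct, "v2": struct})
        model = chem.fit_oplsda(x, y, n_orthogonal=1)
        # the orthogonal loading lives on the structured direction
        assert abs(model.p_ortho[1, 0]) > 0.1
        corr = np.corrcoef(model.t[:, 0], struct)[0, 1]
        assert abs(corr) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_class(self, two_class):
        x, y = two_class
        model = chem.fit_oplsda(x, y, n_orthogonal=2)
        yc = (y == "b").astype(float)
        yc = yc - yc.mean()
        for a in range(model.n_orthogonal):
            t_o = model.t_ortho[:, a]
            assert abs(t_o @ yc) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)

    def test_variance_decomposition_is_exact(self, two_class):
        x, y = two_class
        model = chem.fit_oplsda(x, y, n_orthogonal=1)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        pred = np.outer(model.t[:, 0], model.p[:, 0])
        orth = np.outer(model.t_ortho[:, 0], model.p_ortho[:, 0])
        resid = xc - pred - orth
        total = (xc ** 2).sum()
        modeled = (pred ** 2).sum() + (orth ** 2).sum() + (resid ** 2).sum()
        assert abs(total - modeled) < 1e-8 * total

    def test_three_classes_rejected(self):
        x = pd.DataFrame(np.eye(6))
        y = np.array(["a", "a", "b", "b", "c", "c"])
        with pytest.raises(ModelError, match="PLS-DA"):
            chem.fit_oplsda(x, y)


class TestValidation:
    def test_noiseless_design_reaches_q2_one(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        col = (y == "a").astype(float)
        x = pd.DataFrame({"v1": col, "v2": col, "v3": 1.0 - col})
        report = chem.cross_validate(x, y, chem.ModelSpec("plsda", 1),
                                     folds=3, seed=0)
        assert report.q2 == pytest.approx(1.0, abs=1e-6)
        assert report.r2 == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_labels_give_nonpositive_mean_q2(self):
        """Q2 of label-independent data is <= 0 in expectation."""
        rng = np.random.default_rng(123)
        q2s = []
        for _ in range(200):
            x = pd.DataFrame(rng.normal(size=(8, 4)))
            y = rng.permutation(np.array(["a"] * 4 + ["b"] * 4))
            q2s.append(chem.cross_validate(
                x, y, chem.ModelSpec("plsda", 1), folds=2, seed=1).q2)
        assert np.mean(q2s) < 0.0

    def test_intercept_only_prediction_has_zero_r2(self):
        """R2 = 1 - RSS/TSS: predicting the mean gives exactly 0."""
        target = np.array([0.0, 1.0, 0.0, 1.0])
        tss = ((target - target.mean()) ** 2).sum()
        rss = ((target - target.mean()) ** 2).sum()
        assert 1 - rss / tss == 0.0

    def test_fold_losing_a_class_raises(self):
        x = pd.DataFrame(np.eye(5))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises((StratificationError, ValueError)):
            chem.cross_validate(x, y, chem.ModelSpec("plsda", 1),
                                folds=2, seed=0)

    def test_permutation_p_lower_bound(self, two_class):
        x, y = two_class
        report = chem.permutation_test(x, y, chem.ModelSpec("plsda", 1),
                                       n_permutations=24, folds=2, seed=0)
        assert report.permutation_p >= 1 / 25

    def test_constant_labels_give_p_one(self, two_class):
        x, _ = two_class
        report = chem.permutation_test(x, np.array(["a"] * 8),
                                       chem.ModelSpec("plsda", 1),
                                       n_permutations=10)
        assert report.permutation_p == 1.0

    def test_separated_groups_reach_smallest_p(self):
        """Fold change 8x at 10% CV: no permutation beats the true labels."""
        result = ak.marker_recovery(ak.two_group_spec(
            fold_change=8.0, cv=0.10, seed=17))
        report = chem.permutation_test(
            result["scaled"], result["labels"],
            chem.ModelSpec("oplsda", n_orthogonal=1),
            n_permutations=100, folds=3, seed=17)
        assert report.permutation_p == pytest.approx(1 / 101)
        assert report.q2 > 0.9

    def test_null_rejection_rate_is_calibrated(self):
        """Empirical size of the permutation test near its nominal 5%."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 200
        for i in range(n_sims):
            x = pd.DataFrame(rng.normal(size=(8, 10)))
            y = np.array(["a"] * 4 + ["b"] * 4)
            report = chem.permutation_test(
                x, y, chem.ModelSpec("plsda", 1),
                n_permutations=19, folds=2, seed=i)
            rejections += report.permutation_p <= 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_deterministic_given_seed(self, two_class):
        x, y = two_class
        a = chem.permutation_test(x, y, chem.ModelSpec("plsda", 1),
                                  n_permutations=20, folds=2, seed=5)
        b = chem.permutation_test(x, y, chem.ModelSpec("plsda", 1),
                                  n_permutations=20, folds=2, seed=5)
        assert a.permutation_p == b.permutation_p
        np.testing.assert_array_equal(a.permuted_q2, b.permuted_q2)
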