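import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la

from isocompass.discriminant import (accuracy_from_confusion,
                                     bootstrap_cv_accuracy, confusion_matrix,
                                     consensus_assign, cross_year_predict,
                                     fit_lda, mahalanobis_site_distance,
                                     pool_sites, predict, suggest_pooling,
                                     tolerant_accuracy_from_confusion,
                                     year_shift_test)


def _two_class(rng, sep=10.0, n=30):
    X = np.concatenate([rng.normal(0, 1, (n, 1)), rng.normal(sep, 1, (n, 1))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestFitPredict:
    def test_separable_classes_fully_recovered(self, rng):
        X, y = _two_class(rng)
        model = fit_lda(X, y)
        pred = predict(model, X, true_labels=y)
        assert pred["correct"].all()
        assert model.prop_trace[0] == pytest.approx(1.0)

    def test_identical_classes_have_no_discriminant_signal(self, rng):
        X = rng.normal(size=(80, 3))
        y = np.array(["a", "b"] * 40)
        model = fit_lda(X, y)
        # between-class eigenvalue tiny relative to a separated case
        evals_sep = fit_lda(*_two_class(rng)).prop_trace
        assert model.prop_trace.sum() <= 1.0 + 1e-9
        pred = predict(model, X, true_labels=y)
        assert 0.3 < pred["correct"].mean() < 0.8  # chance-ish

    def test_canonical_axes_match_generalized_eigen_oracle(self, rng):
        # 3 classes in 2-D with hand-computable scatter matrices
        X = np.vstack([rng.normal([0, 0], 1, (20, 2)),
                       rng.normal([4, 0], 1, (20, 2)),
                       rng.normal([0, 4], 1, (20, 2))])
        y = np.repeat(["a", "b", "c"], 20)
        model = fit_lda(X, y)
        # oracle: W^-1 B generalized eigenproblem from scratch
        mus = [X[y == c].mean(0) for c in ("a", "b", "c")]
        grand = X.mean(0)
        W = sum((X[y == c] - m).T @ (X[y == c] - m)
                for c, m in zip(("a", "b", "c"), mus)) / (60 - 3)
        B = sum(20 * np.outer(m - grand, m - grand) for m in mus) / 2
        evals = np.sort(la.eigvalsh(B, W))[::-1]
        prop = evals / evals.sum()
        assert np.allclose(model.prop_trace, prop, atol=1e-8)

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            fit_lda(X, y)

    def test_sample_at_centroid_assigned_there(self, rng):
        X, y = _two_class(rng, sep=4.0)
        model = fit_lda(X, y)
        pred = predict(model, model.centroids)
        assert list(pred["predicted_site"]) == ["a", "b"]
        post = pred[["post_a", "post_b"]].to_numpy()
        assert np.allclose(post.sum(1), 1.0)

    def test_equidistant_tie_broken_lexicographically_and_flagged(self):
        X = np.array([[-1.0], [-1.2], [1.0], [1.2]])
        y = np.array(["b", "b", "a", "a"])
        model = fit_lda(X, y)
        midpoint = model.centroids.mean(0, keepdims=True)
        pred = predict(model, midpoint)
        assert pred["tie"].iloc[0]
        assert pred["predicted_site"].iloc[0] == "a"

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nearest_mahalanobis_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            k, p = rng.integers(2, 5), rng.integers(1, 4)
            X = rng.normal(size=(k * 8, p)) + np.repeat(
                rng.normal(0, 3, (k, p)), 8, axis=0)
            y = np.repeat([f"c{i}" for i in range(k)], 8)
            model = fit_lda(X, y)
            pred = predict(model, X)["predicted_site"].to_numpy()
            Sinv = la.inv(model.pooled_cov)
            d2 = np.array([[(x - m) @ Sinv @ (x - m) for m in model.centroids]
                           for x in X])
            oracle = model.classes[np.argmin(d2, axis=1)]
            assert (pred == oracle).all()

    def test_prop_trace_invariant_under_affine_transform(self, rng):
        X = np.vstack([rng.normal([0, 0, 0], 1, (15, 3)),
                       rng.normal([3, 1, 0], 1, (15, 3)),
                       rng.normal([0, 2, 2], 1, (15, 3))])
        y = np.repeat(["a", "b", "c"], 15)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
        base = fit_lda(X, y).prop_trace
        moved = fit_lda(X @ A + 5.0, y).prop_trace
        assert np.allclose(base, moved, atol=1e-7)


class TestBootstrapCV:
    def test_separated_classes_near_perfect(self, rng):
        X, y = _two_class(rng, sep=12.0)
        cv = bootstrap_cv_accuracy(X, y, n_boot=99, seed=5)
        assert cv.accuracy > 0.98
        assert cv.resubstitution == 1.0

    def test_permuted_labels_drop_to_chance(self, rng):
        X = rng.normal(size=(120, 2))
        y = rng.permutation(np.repeat(["a", "b", "c"], 40))
        cv = bootstrap_cv_accuracy(X, y, n_boot=99, seed=5)
        assert cv.accuracy == pytest.approx(1 / 3, abs=0.1)

    def test_cv_not_better_than_resubstitution_on_average(self):
        diffs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = np.concatenate([rng.normal(0, 1, (15, 2)),
                                rng.normal(1.0, 1, (15, 2))])
            y = np.array(["a"] * 15 + ["b"] * 15)
            cv = bootstrap_cv_accuracy(X, y, n_boot=60, seed=seed)
            diffs.append(cv.resubstitution - cv.accuracy)
        assert np.mean(diffs) >= 0

    def test_loo_alternative_agrees_on_separated_data(self, rng):
        from isocompass.discriminant import loo_cv_accuracy
        X, y = _two_class(rng, sep=12.0)
        assert loo_cv_accuracy(X, y) > 0.98
        Xn = rng.normal(size=(60, 2))
        yn = rng.permutation(np.repeat(["a", "b"], 30))
        assert loo_cv_accuracy(Xn, yn) < 0.75

    def test_requires_seed(self, rng):
        X, y = _two_class(rng)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_cv_accuracy(X, y, n_boot=10, seed=None)


class TestMahalanobisAndPooling:
    def test_distance_in_one_dimension(self):
        # centroids 0 and 3 with pooled variance 9 -> distance 1
        rng = np.random.default_rng(0)
        a = rng.normal(0, 3, 2000)
        b = rng.normal(3, 3, 2000)
        X = np.concatenate([a, b])[:, None]
        y = np.array(["a"] * 2000 + ["b"] * 2000)
        model = fit_lda(X, y)
        D = mahalanobis_site_distance(model)
        expected = abs(model.centroids[0, 0] - model.centroids[1, 0]) / \
            np.sqrt(model.pooled_cov[0, 0])
        assert D.loc["a", "b"] == pytest.approx(expected)
        assert D.loc["a", "b"] == pytest.approx(1.0, abs=0.1)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_identical_centroids_distance_zero(self, rng):
        X = np.tile(rng.normal(size=(20, 2)), (2, 1))
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = fit_lda(X + rng.normal(0, 1e-3, (40, 2)), y)
        D = mahalanobis_site_distance(model)
        assert D.loc["a", "b"] < 0.5

    def test_pool_sites(self):
        labels = pd.Series(["s1", "s2", "s3", "s1"])
        pooled = pool_sites(labels, {"s2": "s1"})
        assert set(pooled) == {"s1", "s3"}
        assert (pool_sites(labels, {}) == labels).all()
        with pytest.raises(ValueError, match="unknown"):
            pool_sites(labels, {"s9": "s1"})

    def test_suggest_pooling_needs_both_closeness(self):
        mahal = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"],
                             columns=["a", "b"])
        near = pd.DataFrame([[0, 0.5], [0.5, 0]], index=["a", "b"],
                            columns=["a", "b"])
        far = near * 10
        assert suggest_pooling(mahal, near) == [("a", "b")]
        assert suggest_pooling(mahal, far) == []


class TestConsensus:
    def _meta(self, pairs):
        return pd.DataFrame([{"sample_id": s, "fish_id": f, "tissue": t}
                             for s, f, t in pairs])

    def _assign(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "correct"])

    def test_three_of_four_is_site_specific(self):
        meta = self._meta([(f"s{i}", "f1", t) for i, t in
                           enumerate(["muscle", "brain", "liver", "eye"])])
        a = self._assign([("s0", True), ("s1", True), ("s2", True),
                          ("s3", False)])
        out = consensus_assign(a, meta)
        assert out["site_specific"].iloc[0]
        assert out["n_correct"].iloc[0] == 3

    def test_two_of_four_is_not(self):
        meta = self._meta([(f"s{i}", "f1", t) for i, t in
                           enumerate(["muscle", "brain", "liver", "eye"])])
        a = self._assign([("s0", True), ("s1", True), ("s2", False),
                          ("s3", False)])
        assert not consensus_assign(a, meta)["site_specific"].iloc[0]

    def test_few_tissues_require_all_correct(self):
        meta = self._meta([("s0", "f1", "muscle"), ("s1", "f1", "brain")])
        half = self._assign([("s0", True), ("s1", False)])
        assert not consensus_assign(half, meta)["site_specific"].iloc[0]
        both = self._assign([("s0", True), ("s1", True)])
        assert consensus_assign(both, meta)["site_specific"].iloc[0]

    def test_unknown_sample_rejected(self):
        meta = self._meta([("s0", "f1", "muscle")])
        with pytest.raises(ValueError, match="missing"):
            consensus_assign(self._assign([("s9", True)]), meta)


class TestConfusionAndCrossYear:
    def test_confusion_row_sums_and_accuracy(self, rng):
        t = rng.choice(["a", "b", "c"], 60)
        p = rng.choice(["a", "b", "c"], 60)
        cm = confusion_matrix(t, p)
        for c in ("a", "b", "c"):
            assert cm.loc[c].sum() == (t == c).sum()
        assert accuracy_from_confusion(cm) == pytest.approx((t == p).mean())

    def test_diagonal_confusion_gives_full_accuracy(self):
        cm = pd.DataFrame(np.diag([3, 4, 5]), index=list("abc"),
                          columns=list("abc"))
        dist = pd.DataFrame(np.ones((3, 3)) * 10 - 10 * np.eye(3),
                            index=list("abc"), columns=list("abc"))
        assert accuracy_from_confusion(cm) == 1.0
        assert tolerant_accuracy_from_confusion(cm, dist) == 1.0

    def test_tolerant_credits_near_sites(self):
        cm = pd.DataFrame([[5, 5], [0, 10]], index=["a", "b"],
                          columns=["a", "b"])
        near = pd.DataFrame([[0, 0.5], [0.5, 0]], index=["a", "b"],
                            columns=["a", "b"])
        far = near * 10
        assert accuracy_from_confusion(cm) == pytest.approx(0.75)
        assert tolerant_accuracy_from_confusion(cm, near, 1.0) == 1.0
        assert tolerant_accuracy_from_confusion(cm, far, 1.0) == pytest.approx(0.75)

    def test_cross_year_on_same_data_dominates(self, paper_shape):
        meta = paper_shape["meta"].set_index("sample_id")
        mat = paper_shape["matrix"]
        mm = meta[(meta["tissue"] == "muscle") & (meta["year"] == 2016)]
        X = mat.loc[mat.index.intersection(mm.index)]
        y = meta.loc[X.index, "site_id"]
        res = cross_year_predict(X, y, X, y, paper_shape["distances"], 1.0)
        assert res.tolerant_accuracy >= res.exact_accuracy
        assert res.exact_accuracy == pytest.approx(
            accuracy_from_confusion(res.confusion))
        assert (res.confusion.sum(axis=1).to_numpy()
                == y.value_counts().sort_index().to_numpy()).all()


class TestYearShift:
    def _data(self, rng, shift=0.0, n=20):
        rows, vals = [], []
        for year in (2016, 2018):
            for i in range(n):
                sid = f"x{year}{i}"
                rows.append((sid, sid, "C. gobio", "muscle", "S01", year))
                vals.append(rng.normal(0, 1) + (shift if year == 2018 else 0))
        meta = pd.DataFrame(rows, columns=["sample_id", "fish_id", "taxon",
                                           "tissue", "site_id", "year"])
        mat = pd.DataFrame({"v": vals}, index=meta["sample_id"])
        return mat, meta

    def test_no_shift_not_significant(self, rng):
        mat, meta = self._data(rng, shift=0.0)
        out = year_shift_test(mat, meta, "v")
        assert abs(out["mean_change"].iloc[0]) < 1.0
        assert not out["significant"].iloc[0]

    def test_injected_shift_detected(self, rng):
        mat, meta = self._data(rng, shift=5.0)
        out = year_shift_test(mat, meta, "v")
        assert out["mean_change"].iloc[0] == pytest.approx(5.0, abs=1.5)
        assert out["p"].iloc[0] < 0.05

    def test_missing_year_cell_omitted_not_raised(self, rng):
        mat, meta = self._data(rng)
        meta2 = meta.copy()
        meta2.loc[meta2["year"] == 2018, "site_id"] = "S02"
        out = year_shift_test(mat, meta2, "v")
        assert len(out) == 0
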