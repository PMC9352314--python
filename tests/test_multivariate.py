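import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la
import scipy.stats as st

from isocompass.multivariate import (anova_type2, canonical_correlation,
                                     emmeans_contrast, holm_adjust,
                                     sidak_adjust, wilks_lambda_test)


def _cca_eig_oracle(X, Y):
    """Brute-force generalized-eigenvalue CCA for cross-checking."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = len(Xc)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = la.solve(Sxx, Sxy) @ la.solve(Syy, Sxy.T)
    evals = np.sort(np.real(la.eigvals(M)))[::-1]
    return np.sqrt(np.clip(evals, 0, 1))


class TestCCA:
    def test_identical_blocks_have_unit_correlations(self, rng):
        X = rng.normal(size=(40, 3))
        res = canonical_correlation(X, X.copy())
        assert np.allclose(res.correlations, 1.0, atol=1e-8)

    def test_independent_noise_has_small_leading_correlation(self, rng):
        X = rng.normal(size=(1000, 2))
        Y = rng.normal(size=(1000, 2))
        res = canonical_correlation(X, Y)
        assert res.correlations[0] < 0.15

    def test_affine_invariance_of_correlations(self, rng):
        X = rng.normal(size=(50, 3))
        Y = X @ rng.normal(size=(3, 2)) + rng.normal(size=(50, 2))
        base = canonical_correlation(X, Y).correlations
        A = np.array([[2.0, 0.3], [0.0, -1.5]])
        transformed = canonical_correlation(X, Y @ A + 7.0).correlations
        assert np.allclose(base, transformed, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generalized_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 5))
        Y = rng.normal(size=(30, 3))
        res = canonical_correlation(X, Y)
        oracle = _cca_eig_oracle(X, Y)[: len(res.correlations)]
        assert np.allclose(res.correlations, oracle, atol=1e-8)

    def test_scores_have_unit_variance_and_stated_correlation(self, rng):
        X = rng.normal(size=(60, 4))
        Y = 0.5 * X[:, :2] + rng.normal(size=(60, 2))
        res = canonical_correlation(X, Y)
        xs = np.asarray(res.x_scores)
        ys = np.asarray(res.y_scores)
        assert np.allclose(xs.var(0, ddof=1), 1.0, atol=1e-8)
        for i, r in enumerate(res.correlations):
            assert np.corrcoef(xs[:, i], ys[:, i])[0, 1] == pytest.approx(
                r, abs=1e-8)

    def test_rank_deficient_block_truncated_with_warning(self, rng):
        X = rng.normal(size=(30, 2))
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])
        Y = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = canonical_correlation(X3, Y)
        assert len(res.correlations) == 2


class TestWilks:
    def test_null_correlations_give_lambda_one(self):
        from isocompass.multivariate import CCAResult
        res = CCAResult(correlations=np.array([0.0, 0.0]), x_coefficients=None,
                        y_coefficients=None, x_scores=None, y_scores=None,
                        n=100, p=2, q=2)
        tests = wilks_lambda_test(res)
        assert tests["wilks_lambda"].iloc[0] == pytest.approx(1.0)
        assert tests["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tests["p"].iloc[0] == pytest.approx(1.0)

    def test_single_pair_equals_correlation_f_test(self, rng):
        n = 40
        x = rng.normal(size=(n, 1))
        y = 0.6 * x + rng.normal(size=(n, 1))
        res = canonical_correlation(x, y)
        tests = wilks_lambda_test(res)
        r2 = res.correlations[0] ** 2
        f_expected = r2 / (1 - r2) * (n - 2)
        assert tests["F"].iloc[0] == pytest.approx(f_expected, rel=1e-10)
        assert tests["df1"].iloc[0] == 1
        assert tests["df2"].iloc[0] == n - 2
        p_expected = float(st.f.sf(f_expected, 1, n - 2))
        assert tests["p"].iloc[0] == pytest.approx(p_expected, rel=1e-10)

    def test_lambda_decreasing_in_any_correlation(self):
        from isocompass.multivariate import CCAResult

        def lam(r):
            res = CCAResult(correlations=np.array(r), x_coefficients=None,
                            y_coefficients=None, x_scores=None, y_scores=None,
                            n=200, p=2, q=2)
            return wilks_lambda_test(res)["wilks_lambda"].iloc[0]

        assert lam([0.8, 0.3]) < lam([0.7, 0.3]) < lam([0.7, 0.2])

    def test_too_small_n_rejected(self):
        from isocompass.multivariate import CCAResult
        res = CCAResult(correlations=np.array([0.5] * 3), x_coefficients=None,
                        y_coefficients=None, x_scores=None, y_scores=None,
                        n=6, p=5, q=5)
        with pytest.raises(ValueError, match="too small"):
            wilks_lambda_test(res)


class TestAnovaType2:
    def _design(self, rng, n=120):
        return pd.DataFrame({
            "site": rng.choice(["A", "B", "C"], n),
            "tissue": rng.choice(["muscle", "liver"], n)})

    def test_site_only_signal_dominates(self, rng):
        design = self._design(rng)
        y = design["site"].map({"A": 0.0, "B": 3.0, "C": 6.0}) + \
            rng.normal(0, 0.5, len(design))
        terms = {a.term: a for a in anova_type2(y, design)}
        assert terms["site"].F > 100
        assert terms["tissue"].F < 5
        assert terms["site"].p_adj <= 1.0

    def test_balanced_design_equals_sequential_ss(self, rng):
        # full 2x2 balanced layout: Type II == Type I for every term
        import statsmodels.formula.api as smf
        import statsmodels.api as sm
        design = pd.DataFrame({"f1": np.repeat(["a", "b"], 20),
                               "f2": np.tile(["x", "y"], 20)})
        y = pd.Series(rng.normal(size=40)) + \
            design["f1"].map({"a": 0, "b": 1.0}).to_numpy()
        res = {a.term: a.sum_sq for a in anova_type2(y, design)}
        df = design.assign(_y=np.asarray(y, float))
        fit = smf.ols("_y ~ C(f1) + C(f2)", data=df).fit()
        seq = sm.stats.anova_lm(fit, typ=1)
        assert res["f1"] == pytest.approx(seq.loc["C(f1)", "sum_sq"])
        assert res["f2"] == pytest.approx(seq.loc["C(f2)", "sum_sq"])

    def test_last_term_type2_equals_type1(self, rng):
        import statsmodels.formula.api as smf
        import statsmodels.api as sm
        design = self._design(rng)
        y = pd.Series(rng.normal(size=len(design)))
        res = {a.term: a.sum_sq for a in anova_type2(y, design)}
        df = design.assign(_y=np.asarray(y, float))
        fit = smf.ols("_y ~ C(site) + C(tissue)", data=df).fit()
        seq = sm.stats.anova_lm(fit, typ=1)
        assert res["tissue"] == pytest.approx(seq.loc["C(tissue)", "sum_sq"])

    def test_permuted_response_kills_signal(self, rng):
        design = self._design(rng)
        y = design["site"].map({"A": 0.0, "B": 3.0, "C": 6.0}) + \
            rng.normal(0, 0.5, len(design))
        perm = pd.Series(rng.permutation(np.asarray(y)))
        terms = {a.term: a for a in anova_type2(perm, design)}
        assert terms["site"].p > 0.001  # signal destroyed

    def test_aliased_factors_rejected(self):
        design = pd.DataFrame({"site": ["A", "A", "B", "B"],
                               "clone": ["A", "A", "B", "B"]})
        with pytest.raises(ValueError, match="aliased"):
            anova_type2(pd.Series([1.0, 2.0, 3.0, 4.0]), design)


class TestAdjustments:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)
        assert sidak_adjust([0.05], m=1)[0] == pytest.approx(0.05)

    def test_holm_stepdown_by_hand(self):
        adj = holm_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_holm_bounds_and_monotonicity(self, rng):
        p = rng.uniform(size=20)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= np.minimum(len(p) * p, 1.0) + 1e-12).all()  # <= Bonferroni
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_sidak_formula(self):
        assert sidak_adjust([0.01], m=5)[0] == pytest.approx(1 - 0.99 ** 5)


class TestEmmeans:
    def test_balanced_design_equals_raw_means(self, rng):
        design = pd.DataFrame({"g": np.repeat(["a", "b"], 16),
                               "h": np.tile(["u", "v"], 16)})
        y = pd.Series(rng.normal(size=32))
        means, _ = emmeans_contrast(y, design, "g")
        raw = pd.Series(np.asarray(y)).groupby(design["g"].values).mean()
        for _, row in means.iterrows():
            assert row["emmean"] == pytest.approx(raw[row["g"]], abs=1e-8)

    def test_recovers_injected_group_difference(self, rng):
        design = pd.DataFrame({"g": np.repeat(["a", "b"], 40)})
        y = pd.Series(rng.normal(size=80) +
                      np.where(design["g"] == "b", 5.0, 0.0))
        means, contrasts = emmeans_contrast(y, design, "g")
        est = contrasts["estimate"].iloc[0]  # a - b
        assert est == pytest.approx(-5.0, abs=1.0)
        assert contrasts["p_adj"].iloc[0] < 0.001
        a = means.set_index("g").loc["a"]
        assert a["ci_low"] < a["emmean"] < a["ci_high"]

    def test_empty_group_rejected(self, rng):
        design = pd.DataFrame({"g": pd.Categorical(["a"] * 4,
                                                   categories=["a", "b"])})
        with pytest.raises(ValueError, match="empty group"):
            emmeans_contrast(pd.Series([1.0, 2.0, 3.0, 4.0]), design, "g")
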