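"""Statistical kernel tests against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import lipidcbm as L
from lipidcbm.stats import autoscale, ttest_matrix


# -- Student t --------------------------------------------------------------

def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestStudentT:
    def test_identical_vectors_are_null(self):
        res = L.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.direction == "zero"

    def test_direction_up_for_shifted_b(self):
        res = L.student_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.direction == "up" and res.p_value < 0.01

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 8)
            res = L.student_t(a, b)
            t, p = pooled_t_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_equals_welch_at_equal_variance_and_size(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 1.5  # identical spread, equal n
        pooled = L.student_t(a, b)
        welch = L.student_t(a, b, welch=True)
        assert pooled.statistic == pytest.approx(welch.statistic, abs=1e-12)
        assert pooled.p_value == pytest.approx(welch.p_value, abs=1e-12)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            L.student_t([1.0], [1.0, 2.0])

    def test_matrix_form_agrees_with_scalar(self, rng):
        xa = rng.normal(size=(7, 5))
        xb = rng.normal(0.3, 1.0, size=(6, 5))
        xa[0, 2] = np.nan
        t, p, diff = ttest_matrix(xa, xb)
        for j in range(5):
            res = L.student_t(xa[:, j], xb[:, j])
            assert t[j] == pytest.approx(res.statistic, abs=1e-12)
            assert p[j] == pytest.approx(res.p_value, abs=1e-12)


# -- thresholds -------------------------------------------------------------

class TestThresholds:
    @pytest.mark.parametrize("n,expected", [(456, 0.00234), (312, 0.00283),
                                            (38, 0.00811), (1, 0.05)])
    def test_sqrt_bonferroni_values(self, n, expected):
        got = L.bonferroni_sqrt_threshold(n)
        assert float(f"{got:.3g}") == expected

    def test_strictly_decreasing_in_n(self):
        vals = [L.bonferroni_sqrt_threshold(n) for n in range(1, 500)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            L.bonferroni_sqrt_threshold(0)

    def test_sidak_closed_form(self):
        assert L.sidak_adjust(0.01, 3) == pytest.approx(0.029701)
        assert L.sidak_adjust(0.2, 1) == 0.2
        assert L.sidak_adjust(0.0, 50) == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 50))
    def test_sidak_bounds(self, p, m):
        adj = L.sidak_adjust(p, m)
        assert p - 1e-15 <= adj <= min(1.0, m * p) + 1e-12


# -- two-way ANOVA ----------------------------------------------------------

def type3_oracle(values, cond, cat):
    """Type III F for each term via explicit sum-coded design matrices and
    full-vs-reduced least-squares fits."""
    values = np.asarray(values, float)
    cond = pd.Categorical(cond)
    cat = pd.Categorical(cat)

    def sum_code(fac):
        levels = list(fac.categories)
        cols = []
        for lev in levels[:-1]:
            col = np.where(fac == lev, 1.0, 0.0)
            col[fac == levels[-1]] = -1.0
            cols.append(col)
        return np.column_stack(cols)

    A = sum_code(cond)
    B = sum_code(cat)
    AB = np.column_stack([A[:, i] * B[:, j]
                          for i in range(A.shape[1]) for j in range(B.shape[1])])
    one = np.ones((len(values), 1))
    full = np.column_stack([one, A, B, AB])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        r = values - X @ beta
        return float(r @ r)

    rss_full = rss(full)
    df_resid = len(values) - full.shape[1]
    out = {}
    for name, drop in (("cond", A), ("cat", B), ("inter", AB)):
        keep = [blk for blk in (A, B, AB) if blk is not drop]
        reduced = np.column_stack([one] + keep)
        ss = rss(reduced) - rss_full
        df = drop.shape[1]
        F = (ss / df) / (rss_full / df_resid)
        out[name] = (ss, F, sps.f.sf(F, df, df_resid))
    return out


class TestTwoWayAnova:
    def test_all_identical_means_is_exact_null(self):
        values = [5.0] * 12
        cond = ["a", "b"] * 6
        cat = ["x"] * 6 + ["y"] * 6
        res = L.two_way_anova(values, cond, cat)
        assert res.f_condition == 0.0 and res.p_condition == 1.0
        assert res.f_interaction == 0.0 and res.p_interaction == 1.0
        assert (res.contrasts["p_sidak"] == 1.0).all()

    def test_planted_condition_effect_matches_oracle(self, rng):
        cond = np.repeat(["a", "b"], 8)
        cat = np.tile(np.repeat(["x", "y"], 4), 2)
        values = rng.normal(size=16) + np.where(cond == "b", 2.0, 0.0)
        res = L.two_way_anova(values, cond, cat)
        oracle = type3_oracle(values, cond, cat)
        assert res.f_condition == pytest.approx(oracle["cond"][1], rel=1e-8)
        assert res.p_condition == pytest.approx(oracle["cond"][2], rel=1e-8)
        assert res.f_interaction == pytest.approx(oracle["inter"][1], rel=1e-6)

    def test_unbalanced_type3_matches_oracle(self, rng):
        cond = np.array(["a"] * 7 + ["b"] * 4)
        cat = np.array(["x", "y", "x", "y", "x", "x", "y",
                        "y", "x", "y", "x"])
        values = rng.normal(size=11) + (cond == "b") * 1.0 + (cat == "y") * 0.5
        res = L.two_way_anova(values, cond, cat)
        oracle = type3_oracle(values, cond, cat)
        assert res.f_condition == pytest.approx(oracle["cond"][1], rel=1e-8)
        assert res.f_category == pytest.approx(oracle["cat"][1], rel=1e-8)
        assert res.f_interaction == pytest.approx(oracle["inter"][1], rel=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(42)
        pvals = []
        cond = np.repeat(["a", "b"], 6)
        cat = np.tile(np.repeat(["x", "y"], 3), 2)
        for _ in range(200):
            res = L.two_way_anova(rng.normal(size=12), cond, cat)
            pvals.append(res.p_condition)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_sidak_contrasts_within_each_category(self, rng):
        cond = np.repeat(["a", "b"], 8)
        cat = np.tile(np.repeat(["x", "y"], 4), 2)
        res = L.two_way_anova(rng.normal(size=16), cond, cat)
        assert set(res.contrasts["category"]) == {"x", "y"}
        assert (res.contrasts["p_sidak"] >= res.contrasts["p_raw"] - 1e-15).all()


# -- PCA outlier exclusion --------------------------------------------------

class TestPcaOutliers:
    def test_tight_cluster_rarely_excluded(self, rng):
        X = rng.normal(size=(20, 10))
        excluded = L.pca_outlier_exclusion(X)
        assert len(excluded) <= 2  # expected rate ~5% of 20

    def test_displaced_sample_excluded(self, rng):
        X = rng.normal(size=(20, 10))
        direction = rng.normal(size=10)
        X[7] += 10 * direction / np.linalg.norm(direction) * X.std()
        excluded = L.pca_outlier_exclusion(X, sample_ids=list("abcdefghijklmnopqrst"))
        assert "h" in excluded

    def test_invariant_to_variable_scaling(self, rng):
        X = rng.normal(size=(15, 8))
        X[3] += 6.0
        scale = rng.uniform(0.1, 50.0, size=8)
        assert (L.pca_outlier_exclusion(X)
                == L.pca_outlier_exclusion(X * scale))

    def test_too_few_samples_skips(self, rng):
        with pytest.warns(UserWarning):
            assert L.pca_outlier_exclusion(rng.normal(size=(3, 5))) == []


# -- sparse PLS-DA ----------------------------------------------------------

class TestSplsda:
    @pytest.fixture
    def toy(self, rng):
        X = rng.normal(size=(16, 20))
        y = np.array(["a"] * 8 + ["b"] * 8)
        X[y == "b"] += rng.normal(0.4, 0.2, size=20)
        return pd.DataFrame(X, columns=[f"v{i}" for i in range(20)]), y

    def test_dense_limit_reproduces_pls_scores(self, toy):
        from sklearn.cross_decomposition import PLSRegression
        X, y = toy
        model = L.splsda_select(X, y, n_components=2, keepx=X.shape[1])
        assert set(model.selected_variables) == set(X.columns)
        ref = PLSRegression(n_components=2, scale=True).fit(
            X.to_numpy(), (y == "b").astype(float))
        t1 = model.scores["comp1"].to_numpy()
        r1 = ref.x_scores_[:, 0]
        cos = abs(t1 @ r1) / (np.linalg.norm(t1) * np.linalg.norm(r1))
        assert cos > 1 - 1e-8

    def test_informative_variable_selected(self, rng):
        X = rng.normal(size=(16, 40))
        y = np.array(["a"] * 8 + ["b"] * 8)
        X[y == "b", 11] += 3.0
        Xdf = pd.DataFrame(X, columns=[f"v{i}" for i in range(40)])
        model = L.splsda_select(Xdf, y, n_components=2, keepx=5)
        assert "v11" in model.selected_variables
        # oracle: the top |loading| of dense PLS is the informative variable
        dense = L.splsda_select(Xdf, y, n_components=1, keepx=40)
        assert dense.loadings["comp1"].abs().idxmax() == "v11"

    def test_keepx_bounds_support_size(self, toy):
        X, y = toy
        model = L.splsda_select(X, y, n_components=2, keepx=[3, 7])
        nz = (model.loadings != 0).sum()
        assert nz["comp1"] <= 3 and nz["comp2"] <= 7

    def test_loadings_unit_norm_and_scores_orthogonal(self, toy):
        X, y = toy
        model = L.splsda_select(X, y, n_components=2, keepx=6)
        for c in model.loadings:
            assert np.linalg.norm(model.loadings[c]) == pytest.approx(1.0)
        dot = model.scores["comp1"] @ model.scores["comp2"]
        assert abs(dot) < 1e-8

    def test_label_symmetry(self, toy):
        X, y = toy
        m1 = L.splsda_select(X, y, n_components=2, keepx=6)
        flipped = np.where(y == "a", "b", "a")
        m2 = L.splsda_select(X, flipped, n_components=2, keepx=6)
        assert set(m1.selected_variables) == set(m2.selected_variables)

    def test_constant_columns_dropped_with_warning(self, toy):
        X, y = toy
        X = X.copy()
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = L.splsda_select(X, y, n_components=1, keepx=X.shape[1])
        assert model.dropped_constant == ["const"]

    def test_orientation_second_class_positive(self, toy):
        X, y = toy
        model = L.splsda_select(X, y, n_components=1, keepx=X.shape[1])
        assert model.scores.loc[np.asarray(y) == "b", "comp1"].mean() > 0


# -- Pearson matrices -------------------------------------------------------

class TestPearsonMatrix:
    def test_self_correlation_is_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 10)),
                            index=["g1", "g2", "g3", "g4"])
        r, p, sig = L.pearson_matrix(expr)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_perfect_anticorrelation(self):
        expr = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b"],
                            dtype=float)
        r, p, sig = L.pearson_matrix(expr, threshold=1e-6)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] == 0.0
        assert bool(sig.loc["a", "b"])

    def test_matches_covariance_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 15)))
        r, p, sig = L.pearson_matrix(expr)
        X = expr.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T
        d = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(d, d)
        np.testing.assert_allclose(r.to_numpy(), oracle, atol=1e-12)

    def test_insufficient_pairs_undetermined(self):
        expr = pd.DataFrame([[1.0, 2.0, np.nan, np.nan],
                             [np.nan, np.nan, 1.0, 2.0]], index=["a", "b"])
        r, p, sig = L.pearson_matrix(expr)
        assert np.isnan(r.loc["a", "b"]) and not bool(sig.loc["a", "b"])
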