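import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from tweetfacets.community_profile import TABLE_COLUMNS
from tweetfacets.facet_correlation import (
    CONTENT_VARS,
    ENGAGEMENT_VARS,
    USER_VARS,
    ProfileMatrix,
    adjusted_canonical_correlation,
    canonical_loadings,
    cca_first,
    drop_totals,
    filter_communities,
    pairwise_engagement_correlation,
    pearson,
    permutation_null,
    pooled_adjusted_correlation,
    quartile_engagement_summary,
    rank_communities,
    standardize,
)


def _fake_profiles(n, rng=None, tweets=500, users=200):
    rng = rng or np.random.default_rng(0)
    data = {c: rng.normal(size=n) for c in TABLE_COLUMNS}
    data["total_tweets"] = np.full(n, tweets)
    data["total_users"] = np.full(n, users)
    df = pd.DataFrame(data, index=[f"c{i:03d}" for i in range(n)])[TABLE_COLUMNS]
    return df


class TestFilterCommunities:
    def test_exclusion_rule(self):
        df = _fake_profiles(3)
        df["total_tweets"] = [99, 500, 100]
        df["total_users"] = [200, 49, 50]
        kept = filter_communities(df)
        # "fewer than 100 tweets or 50 users" is strict: the boundary survives
        assert list(kept.index) == ["c002"]

    def test_all_excluded_raises(self):
        df = _fake_profiles(2, tweets=10, users=10)
        with pytest.raises(ValueError, match="lower"):
            filter_communities(df)


class TestDropTotals:
    def test_removes_two_size_columns(self):
        df = _fake_profiles(5)
        out = drop_totals(df)
        assert out.shape[1] == len(TABLE_COLUMNS) - 2
        assert "total_tweets" not in out and "total_users" not in out

    def test_idempotent_and_tags_preserved(self):
        df = drop_totals(_fake_profiles(5))
        again = drop_totals(df)
        assert again.equals(df)
        pm = ProfileMatrix(again)
        assert set(pm.facets.values()) == {"engagement", "user", "content"}


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert np.allclose(standardize(df)["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self, caplog):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 4.0]})
        with caplog.at_level("WARNING"):
            z = standardize(df)
        assert (z["a"] == 0).all()
        assert "zero-variance" in caplog.text

    def test_idempotent(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(20, 3)),
                          columns=list("abc"))
        once = standardize(df)
        assert np.allclose(standardize(once), once)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0]}))


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, -1, 1, -1], [1, 1, -1, -1], 0.0),
    ])
    def test_reference_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))


class TestPairwise:
    def test_duplicated_column_reaches_unity(self):
        df = drop_totals(_fake_profiles(30))
        df["mean_unique_words"] = df["pct_like"]
        tab = pairwise_engagement_correlation(ProfileMatrix(standardize(df)))
        top = tab.iloc[0]
        assert (top["engagement_var"], top["other_var"]) == ("pct_like", "mean_unique_words")
        assert top["r"] == pytest.approx(1.0)

    def test_engagement_only_matrix_is_empty(self):
        df = drop_totals(_fake_profiles(10))[ENGAGEMENT_VARS]
        assert pairwise_engagement_correlation(ProfileMatrix(df)).empty

    def test_independent_columns_stay_below_null_bound(self):
        df = drop_totals(_fake_profiles(1000, rng=np.random.default_rng(7)))
        tab = pairwise_engagement_correlation(ProfileMatrix(standardize(df)))
        assert (tab["r"].abs() < 0.1).all()

    def test_table_shape(self):
        df = drop_totals(_fake_profiles(25))
        tab = pairwise_engagement_correlation(ProfileMatrix(df))
        assert len(tab) == len(ENGAGEMENT_VARS) * (len(USER_VARS) + len(CONTENT_VARS))


def _planted_blocks(n, rho, rng, p=3, q=2, noise=0.1):
    """Blocks whose population first canonical correlation is ~rho."""
    z = rng.normal(size=n)
    u = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
    X = pd.DataFrame({f"x{j}": z + noise * rng.normal(size=n) for j in range(p)})
    Y = pd.DataFrame({f"y{j}": u + noise * rng.normal(size=n) for j in range(q)})
    return X, Y


def _brute_force_cca_r(X, Y, rng, restarts=8):
    """Derivative-free maximization of corr(Xa, Yb); independent oracle."""
    Xc = np.asarray(X) - np.asarray(X).mean(0)
    Yc = np.asarray(Y) - np.asarray(Y).mean(0)
    p, q = Xc.shape[1], Yc.shape[1]

    def neg_corr(theta):
        a, b = theta[:p], theta[p:]
        cx, cy = Xc @ a, Yc @ b
        sx, sy = cx.std(), cy.std()
        if sx < 1e-12 or sy < 1e-12:
            return 0.0
        return -abs(np.corrcoef(cx, cy)[0, 1])

    best = 0.0
    for _ in range(restarts):
        x0 = rng.normal(size=p + q)
        res = scipy.optimize.minimize(neg_corr, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12,
                                               "maxiter": 5000})
        best = max(best, -res.fun)
    return best


class TestCcaFirst:
    def test_self_correlated_single_column(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        Y = pd.DataFrame({"y": X["a"]})
        res = cca_first(X, Y)
        assert res.r == pytest.approx(1.0, abs=1e-8)
        assert res.weights_x.abs().idxmax() == "a"

    def test_planted_population_correlation(self):
        rng = np.random.default_rng(11)
        X, Y = _planted_blocks(5000, 0.8, rng)
        res = cca_first(standardize(X), standardize(Y))
        assert res.r == pytest.approx(0.8, abs=0.03)

    def test_matches_derivative_free_optimizer(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x0", "x1", "x2"])
            Y = pd.DataFrame(rng.normal(size=(40, 2)), columns=["y0", "y1"])
            r_eig = cca_first(X, Y, ridge=0.0).r
            r_opt = _brute_force_cca_r(X, Y, rng)
            assert abs(r_eig - r_opt) < 1e-4

    def test_matches_sklearn(self):
        from sklearn.cross_decomposition import CCA as SkCCA
        rng = np.random.default_rng(3)
        X, Y = _planted_blocks(300, 0.6, rng)
        res = cca_first(standardize(X), standardize(Y))
        sk = SkCCA(n_components=1, scale=True).fit(X, Y)
        u, v = sk.transform(X, Y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert res.r == pytest.approx(r_sk, abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("de"))
        base = cca_first(X, Y).r
        X2 = X * np.array([3.0, -0.2, 17.0]) + np.array([5.0, -1.0, 0.3])
        Y2 = Y * np.array([-4.0, 0.01]) + 100.0
        assert cca_first(X2, Y2).r == pytest.approx(base, abs=1e-8)

    def test_r_bounds_pairwise_pearson(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
            Y = pd.DataFrame(rng.normal(size=(60, 2)), columns=list("de"))
            r = cca_first(X, Y).r
            best_pair = max(abs(pearson(X[a], Y[b])) for a in X for b in Y)
            assert r >= best_pair - 1e-10

    def test_variates_reproduce_r_and_unit_variance(self):
        rng = np.random.default_rng(21)
        X, Y = _planted_blocks(200, 0.5, rng)
        res = cca_first(standardize(X), standardize(Y))
        # the default relative ridge perturbs r at ~1e-8
        assert np.corrcoef(res.variate_x, res.variate_y)[0, 1] == \
            pytest.approx(res.r, abs=1e-6)
        assert res.variate_x.std(ddof=1) == pytest.approx(1.0, abs=1e-6)
        assert res.variate_y.std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficient_names_columns(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["good", "dup"])
        X["dup"] = X["good"]
        Y = pd.DataFrame(rng.normal(size=(40, 2)), columns=list("de"))
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            cca_first(X, Y, ridge=0.0)


class TestLoadings:
    def test_single_column_block(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        Y = pd.DataFrame({"y": rng.normal(size=50)})
        res = cca_first(pd.concat([X, pd.DataFrame({"x2": rng.normal(size=50)})], axis=1), Y)
        assert abs(res.loadings_y["y"]) == pytest.approx(1.0, abs=1e-10)

    def test_identity_with_correlation_matrix(self):
        # for standardized X with unit-variance variate: loadings = R @ a
        rng = np.random.default_rng(4)
        X, Y = _planted_blocks(150, 0.4, rng)
        Xz, Yz = standardize(X), standardize(Y)
        res = cca_first(Xz, Yz)
        R = np.corrcoef(np.asarray(Xz), rowvar=False)
        predicted = R @ res.weights_x.to_numpy()
        assert np.allclose(res.loadings_x.to_numpy(), predicted, atol=1e-6)

    def test_bounded(self):
        rng = np.random.default_rng(8)
        X, Y = _planted_blocks(80, 0.7, rng)
        res = cca_first(standardize(X), standardize(Y))
        for s in (res.loadings_x, res.loadings_y):
            assert (s.abs() <= 1 + 1e-12).all()


class TestPermutationNull:
    def test_detects_real_signal(self):
        rng = np.random.default_rng(6)
        X, Y = _planted_blocks(200, 0.7, rng)
        r = cca_first(X, Y).r
        null = permutation_null(X, Y, n_perm=199, rng=0)
        p = (1 + np.sum(null >= r)) / 200
        assert p < 0.01

    def test_adjustment_zeroes_null_level(self):
        null = np.full(99, 0.3)
        assert adjusted_canonical_correlation(0.3, null) == pytest.approx(0.0, abs=1e-6)
        assert adjusted_canonical_correlation(1.0, null) == pytest.approx(1.0)

    def test_pooled_estimator(self):
        assert pooled_adjusted_correlation([0.3, 0.3], [0.09, 0.09]) == 0.0
        assert pooled_adjusted_correlation([1.0], [0.25]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pooled_adjusted_correlation([], [])

    def test_stratified_permutation_stays_within_bands(self):
        rng = np.random.default_rng(10)
        X, Y = _planted_blocks(60, 0.0, rng)
        sizes = np.arange(60)
        null = permutation_null(X, Y, n_perm=5, rng=1, strata=sizes, n_strata=6)
        assert null.shape == (5,)
        assert np.all((null >= 0) & (null <= 1))


class TestQuartileSummary:
    def _profiles(self):
        df = _fake_profiles(8)
        df["pct_like"] = np.arange(10.0, 90.0, 10.0)
        df["total_users"] = 100
        return df

    def test_even_bands(self):
        out = quartile_engagement_summary(self._profiles(), "pct_like")
        assert list(out["n_communities"]) == [2, 2, 2, 2]
        assert (out["mean_total_users"] == 100).all()

    def test_permutation_invariant(self):
        df = self._profiles()
        shuffled = df.sample(frac=1.0, random_state=0)
        a = quartile_engagement_summary(df, "pct_like")
        b = quartile_engagement_summary(shuffled, "pct_like")
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_communities(self):
        with pytest.raises(ValueError):
            quartile_engagement_summary(_fake_profiles(3), "pct_like")


class TestRankings:
    def _df(self, tweets):
        df = _fake_profiles(len(tweets))
        df["total_tweets"] = tweets
        return df

    def test_top_and_bottom(self):
        df = self._df([5, 10, 1])
        top, bottom = rank_communities(df, by="tweets", k=1)
        assert top["condition"].tolist() == ["c001"]
        assert bottom["condition"].tolist() == ["c002"]

    def test_alphabetical_tie_break(self):
        df = self._df([7, 7, 1, 1])
        top, bottom = rank_communities(df, by="tweets", k=2)
        assert top["condition"].tolist() == ["c000", "c001"]
        assert bottom["condition"].tolist() == ["c002", "c003"]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            rank_communities(self._df([1, 2, 3]), k=2)
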