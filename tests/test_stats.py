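"""Inferential chain: multivariate comparison, logistic/ROC, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from occireach import stats
from occireach.errors import (
    InvalidArgumentError,
    NoSolutionError,
    UndefinedStatisticError,
)
from occireach.stats import (
    PowerSpec,
    binomial_min_n,
    delong_auc_test,
    kruskal_wallis,
    logistic_fit,
    manova_rm,
    roc_analysis,
    shapiro_wilk,
    youden_j,
)


def _table(y, X, sides=None):
    df = pd.DataFrame(X, columns=[f"dv{i}" for i in range(X.shape[1])])
    df["side"] = sides if sides is not None else np.where(y == 1, "paralyzed",
                                                          "non_paralyzed")
    return df


class TestManova:
    def test_mirrored_groups_lambda_one(self):
        pts = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 4.0], [0.0, 3.0]])
        X = np.vstack([pts, pts])  # identical multivariate means
        y = np.repeat([0, 1], 4)
        res = manova_rm(_table(y, X), ["dv0", "dv1"], covariates=[])
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-10)
        assert res.F == pytest.approx(0.0, abs=1e-8)

    def test_single_dv_equals_oneway_anova(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 12)
        X = np.concatenate([a, b])[:, None]
        y = np.repeat([0, 1], [15, 12])
        res = manova_rm(_table(y, X), ["dv0"], covariates=[])
        f_ref, p_ref = sps.f_oneway(a, b)
        assert res.F == pytest.approx(f_ref, rel=1e-8)
        assert res.p == pytest.approx(p_ref, rel=1e-6)
        assert res.univariate.loc["dv0", "F"] == pytest.approx(f_ref, rel=1e-8)

    def test_two_group_lambda_matches_hotelling(self, rng):
        """Wilks' lambda equals 1 / (1 + T^2 / (n - 2)) for two groups."""
        n1, n2 = 12, 14
        A = rng.normal(0, 1, (n1, 2))
        B = rng.normal(0.9, 1, (n2, 2))
        X = np.vstack([A, B])
        y = np.repeat([0, 1], [n1, n2])
        res = manova_rm(_table(y, X), ["dv0", "dv1"], covariates=[])
        diff = A.mean(0) - B.mean(0)
        S = (((A - A.mean(0)).T @ (A - A.mean(0)))
             + ((B - B.mean(0)).T @ (B - B.mean(0)))) / (n1 + n2 - 2)
        t2 = n1 * n2 / (n1 + n2) * diff @ np.linalg.solve(S, diff)
        assert res.wilks_lambda == pytest.approx(1 / (1 + t2 / (n1 + n2 - 2)),
                                                 rel=1e-8)

    def test_matches_statsmodels_manova_with_covariates(self, rng):
        """Independent cross-check of lambda/F/df against statsmodels."""
        from statsmodels.multivariate.manova import MANOVA

        n = 40
        df = pd.DataFrame({
            "dv0": rng.normal(size=n), "dv1": rng.normal(size=n),
            "dv2": rng.normal(size=n),
            "side": np.repeat(["paralyzed", "non_paralyzed"], n // 2),
            "age": rng.normal(50, 8, n), "bmi": rng.normal(24, 3, n),
        })
        df.loc[df.side == "paralyzed", "dv0"] += 1.0
        res = manova_rm(df, ["dv0", "dv1", "dv2"], covariates=["age", "bmi"])
        ref = MANOVA.from_formula(
            "dv0 + dv1 + dv2 ~ C(side) + age + bmi", data=df
        ).mv_test().results["C(side)"]["stat"].loc["Wilks' lambda"]
        assert res.wilks_lambda == pytest.approx(float(ref["Value"]), rel=1e-8)
        assert res.F == pytest.approx(float(ref["F Value"]), rel=1e-8)
        assert (res.df1, res.df2) == (int(ref["Num DF"]), int(ref["Den DF"]))
        assert res.p == pytest.approx(float(ref["Pr > F"]), rel=1e-6)

    def test_order_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 0, 1  # both classes guaranteed
        df = _table(y, X)
        perm = rng.permutation(30)
        res1 = manova_rm(df, ["dv0", "dv1", "dv2"], covariates=[])
        res2 = manova_rm(df.iloc[perm].reset_index(drop=True),
                         ["dv0", "dv1", "dv2"], covariates=[])
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, rel=1e-10)
        assert res1.p == pytest.approx(res2.p, rel=1e-8)


class TestNormalityRouting:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([1, 2, 3, 4], [1, 2, 3, 4])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_matches_hand_rank_enumeration(self):
        # ranks 1..6; R1 = 6, R2 = 15; H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1)
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        expected = 12 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
        assert h == pytest.approx(expected, rel=1e-12)

    def test_shapiro_matches_reference_values(self):
        # frozen oracle: R's shapiro.test on these exact samples
        x = np.round(np.random.default_rng(777).normal(size=50), 6)
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.9829892210, abs=1e-3)
        assert p == pytest.approx(0.6829150018, abs=1e-3)
        w2, p2 = shapiro_wilk(x[:25] ** 2)
        assert w2 == pytest.approx(0.8625197871, abs=1e-3)
        assert p2 == pytest.approx(0.0030731610, abs=1e-3)

    def test_constant_sample_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            shapiro_wilk(np.ones(10))
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis([2, 2], [2, 2])

    def test_gate_routes_nonnormal_to_kruskal(self, rng):
        n = 60
        df = pd.DataFrame({
            "normal_dv": rng.normal(size=n),
            "skewed_dv": rng.lognormal(0, 1.5, size=n),
            "side": np.repeat(["paralyzed", "non_paralyzed"], n // 2),
        })
        routed = stats.normality_gated_tests(df, ["normal_dv", "skewed_dv"])
        assert routed.loc["normal_dv", "test"] == "anova"
        assert routed.loc["skewed_dv", "test"] == "kruskal_wallis"


def _newton_logistic(X, y, tol=1e-12, iters=200):
    """Independent Newton-Raphson oracle for logistic regression."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(iters):
        mu = 1 / (1 + np.exp(-Xd @ beta))
        W = mu * (1 - mu)
        grad = Xd.T @ (y - mu)
        hess = (Xd * W[:, None]).T @ Xd
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestLogistic:
    def test_balanced_intercept_only_null_deviance(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        fit = logistic_fit(y, X)
        assert fit.null_deviance == pytest.approx(2 * n * np.log(2), rel=1e-9)

    def test_matches_newton_oracle(self, rng):
        n = 20
        X = rng.normal(size=(n, 2))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        fit = logistic_fit(y, pd.DataFrame(X, columns=["a", "b"]))
        beta = _newton_logistic(X, y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_independent_predictor_null_model(self, rng):
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        fit = logistic_fit(y, X)
        assert fit.chi2 < 6.0           # ~chi2(1) under the null
        assert fit.mcfadden_r2 < 0.02

    def test_aic_identity(self, rng):
        y = np.repeat([0, 1], 15).astype(float)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        fit = logistic_fit(y, X)
        assert fit.aic == pytest.approx(fit.deviance + 2 * 2, rel=1e-12)

    def test_covariate_never_increases_deviance(self, rng):
        n = 60
        y = rng.integers(0, 2, n).astype(float)
        y[:2], y[-2:] = 0, 1
        X = pd.DataFrame({"x": rng.normal(size=n)})
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        assert (logistic_fit(y, X, cov).deviance
                <= logistic_fit(y, X).deviance + 1e-6)

    def test_separated_data_flagged(self):
        y = np.repeat([0.0, 1.0], 10)
        X = pd.DataFrame({"x": np.arange(20.0)})
        fit = logistic_fit(y, X)
        assert fit.separation_flag

    def test_degenerate_y_rejected(self):
        with pytest.raises(InvalidArgumentError):
            logistic_fit(np.zeros(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestRoc:
    def test_youden_from_operating_point(self):
        assert youden_j(0.80, 0.98) == pytest.approx(0.78)
        with pytest.raises(InvalidArgumentError):
            youden_j(1.2, 0.5)

    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = roc_analysis(scores, labels)
        assert res.cutoff_youden == pytest.approx(1.0)
        assert res.auc == pytest.approx(1.0)
        assert res.cutoff == 10.0  # lowest threshold attaining max J

    def test_auc_equals_mann_whitney(self, rng):
        """Trapezoidal AUC equals U / (n1 n2) with half-credit ties."""
        for _ in range(100):
            n1 = int(rng.integers(3, 12))
            n0 = int(rng.integers(3, 12))
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            res = roc_analysis(scores, labels)
            pos, neg = scores[:n1], scores[n1:]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-10)

    def test_cutoff_maximizes_j_exhaustively(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2], labels[-2:] = 1, 0
        res = roc_analysis(scores, labels)
        assert res.cutoff_youden == pytest.approx(res.youden.max())
        assert np.all(res.cutoff_youden >= res.youden - 1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2], labels[-2:] = 1, 0
        base = roc_analysis(scores, labels).auc
        for fn in (np.exp, lambda s: s ** 3, lambda s: 5 * s - 2):
            assert roc_analysis(fn(scores), labels).auc == pytest.approx(base)

    def test_inverted_discriminator_reported_below_half(self, rng):
        # paralyzed side scores LOWER: fixed direction must report AUC < 0.5
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        labels = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        assert roc_analysis(scores, labels).auc < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_analysis(np.arange(5.0), np.ones(5, int))


class TestDelong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2], labels[-2:] = 1, 0
        auc_a, auc_b, var, z, p = delong_auc_test(scores, scores, labels)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_null_scores_auc_near_half(self, rng):
        n = 2000
        labels = rng.integers(0, 2, n)
        auc_a, auc_b, *_ = delong_auc_test(rng.normal(size=n),
                                           rng.normal(size=n), labels)
        assert auc_a == pytest.approx(0.5, abs=0.05)
        assert auc_b == pytest.approx(0.5, abs=0.05)

    def test_variance_close_to_bootstrap(self, rng):
        """Analytic AUC variance tracks a bootstrap estimate within 20%."""
        n = 50
        labels = np.repeat([1, 0], n // 2)
        scores = np.where(labels == 1, rng.normal(1, 1, n), rng.normal(0, 1, n))
        se = stats._delong_auc_se(scores, labels)
        boots = []
        for _ in range(2000):
            idx1 = rng.integers(0, n // 2, n // 2)
            idx0 = n // 2 + rng.integers(0, n // 2, n // 2)
            s = np.concatenate([scores[idx1], scores[idx0]])
            pos, neg = s[:n // 2], s[n // 2:]
            u = np.mean(pos[:, None] > neg[None, :]) \
                + 0.5 * np.mean(pos[:, None] == neg[None, :])
            boots.append(u)
        assert se == pytest.approx(np.std(boots), rel=0.2)


class TestBinomialPower:
    def test_study_design_returns_eight(self):
        n, c, power = binomial_min_n(PowerSpec(p0=0.5, g=0.4, alpha=0.05,
                                               power=0.8))
        assert n == 8
        assert c == 7
        assert power == pytest.approx(0.8131, abs=5e-4)

    def test_certain_alternative_enumeration(self):
        # p1 = 1.0: first n with one-sided size <= 0.05 is n = 5 (2^-5)
        n, c, power = binomial_min_n(PowerSpec(p0=0.5, g=0.5))
        assert (n, c) == (5, 5)
        assert power == 1.0

    def test_exactness_against_direct_enumeration(self):
        spec = PowerSpec(p0=0.3, g=0.3, alpha=0.05, power=0.8)
        n, c, power = binomial_min_n(spec)
        size = float(sps.binom.sf(c - 1, n, 0.3))
        assert size <= 0.05
        assert float(sps.binom.sf(c - 1, n, 0.6)) == pytest.approx(power)
        # no smaller n achieves the power with a valid critical value
        for m in range(1, n):
            tails = sps.binom.sf(np.arange(m + 1) - 1, m, 0.3)
            valid = np.flatnonzero(tails <= 0.05)
            if valid.size:
                assert float(sps.binom.sf(valid[0] - 1, m, 0.6)) < 0.8

    def test_zero_effect_no_solution(self):
        with pytest.raises(NoSolutionError):
            binomial_min_n(PowerSpec(g=0.0))
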