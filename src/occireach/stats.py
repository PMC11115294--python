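"""Inferential chain for paralyzed vs non-paralyzed side discrimination.

The chain mirrors a common clinical-kinematics workflow: a covariate-
adjusted multivariate comparison of the feature set between sides (Wilks'
lambda), univariate follow-ups with eta-squared effect sizes, a normality
gate that routes non-normal variables to a Kruskal-Wallis comparison,
binomial logistic regression per candidate feature, ROC analysis with
Youden-index cutoffs, DeLong comparison of correlated AUCs, and the exact
one-sample binomial power calculation used for sample-size planning.

Repeated trials are treated as independent observations (the pooled-trial
design): with 100 trials, 7 dependent variables and 6 covariates the
multivariate side test carries F with (7, 86) degrees of freedom.

The ROC direction is fixed: higher scores predict the paralyzed side for
every feature.  Features on which the paralyzed side scores *lower* (e.g.
peak elbow flexion) therefore produce AUC values below 0.5, which are
reported as-is rather than silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InvalidArgumentError,
    NoSolutionError,
    RankDeficiencyError,
    UndefinedStatisticError,
)
from .trial import PARALYZED

DEFAULT_COVARIATES = ["sex", "age", "bmi", "months_post_onset",
                      "disp_manubrium", "disp_occiput"]


def _encode(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric design columns; 'sex'-like object columns become 0/1."""
    out = {}
    for c in cols:
        s = df[c]
        if s.dtype == object or str(s.dtype) == "category":
            codes = pd.Categorical(s).codes.astype(float)
            out[c] = codes
        else:
            out[c] = s.astype(float).to_numpy()
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# multivariate side comparison
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float
    univariate: pd.DataFrame  # per-DV F, p, eta_squared


def manova_rm(table: pd.DataFrame, dvs: list[str], factor: str = "side",
              covariates: list[str] | None = None) -> ManovaResult:
    """Covariate-adjusted multivariate test of ``factor`` on the DV set.

    Wilks' lambda via the multivariate linear model (intercept + factor +
    covariates): lambda = det(E) / det(E + H) with E the residual SSCP of
    the full model and H the extra SSCP explained by the factor.  For a
    single-df factor the F transform is exact:
    F = (1 - lambda)/lambda * (v - p + 1)/p with v the residual df and p
    the number of DVs; trials are treated as observations.  Also returns
    per-DV univariate F and classical eta-squared (effect SS / total SS)
    from the same adjusted model.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    data = table[dvs + [factor]].copy()
    cov_df = _encode(table, covariates) if covariates else pd.DataFrame(index=table.index)
    if data[dvs].isna().any().any() or cov_df.isna().any().any():
        raise InvalidArgumentError("feature table contains missing values")
    counts = data[factor].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise InvalidArgumentError("need >= 2 observations in each factor level")

    Y = data[dvs].to_numpy(dtype=float)
    n, p = Y.shape
    group = pd.get_dummies(data[factor], drop_first=True, dtype=float).to_numpy()
    cov = cov_df.to_numpy(dtype=float) if len(cov_df.columns) else np.empty((n, 0))
    X_full = np.column_stack([np.ones(n), group, cov])
    X_red = np.column_stack([np.ones(n), cov])
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        raise RankDeficiencyError("collinear design (factor + covariates)")

    def _resid_sscp(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R, R

    E, resid_full = _resid_sscp(X_full)
    E_red, _ = _resid_sscp(X_red)
    H = E_red - E
    v = n - rank_full                      # residual df
    if v - p + 1 <= 0:
        raise InvalidArgumentError("too few observations for the DV count")
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_t <= 0:
        raise RankDeficiencyError("singular within-group covariance matrix")
    wilks = float(np.exp(logdet_e - logdet_t))

    df1, df2 = p, v - p + 1                # exact for a one-df hypothesis
    f_val = (1.0 - wilks) / wilks * df2 / df1
    p_val = float(sps.f.sf(f_val, df1, df2))

    # univariate follow-ups on the same adjusted design
    mse = np.diag(E) / v
    rows = []
    for j, dv in enumerate(dvs):
        ss_effect = float(H[j, j])
        ss_total = float(np.sum((Y[:, j] - Y[:, j].mean()) ** 2))
        f_uni = ss_effect / mse[j]
        rows.append({"dv": dv, "F": f_uni,
                     "p": float(sps.f.sf(f_uni, 1, v)),
                     "eta_squared": ss_effect / ss_total})
    return ManovaResult(
        wilks_lambda=wilks, F=float(f_val), df1=df1, df2=df2, p=p_val,
        univariate=pd.DataFrame(rows).set_index("dv"),
    )


# ---------------------------------------------------------------------------
# distributional checks
# ---------------------------------------------------------------------------

def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); errors on constant samples."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise InvalidArgumentError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("Shapiro-Wilk undefined for constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction."""
    if len(groups) < 2:
        raise InvalidArgumentError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise UndefinedStatisticError("Kruskal-Wallis undefined: all values tied")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def normality_gated_tests(table: pd.DataFrame, dvs: list[str],
                          factor: str = "side", alpha: float = 0.05,
                          ) -> pd.DataFrame:
    """Route each DV to Kruskal-Wallis when Shapiro-Wilk rejects normality.

    Returns one row per DV: the chosen test, its statistic and p-value.
    """
    rows = []
    for dv in dvs:
        x = table[dv].to_numpy(dtype=float)
        w, p_sw = shapiro_wilk(x)
        groups = [g[dv].to_numpy(dtype=float)
                  for _, g in table.groupby(factor, observed=True)]
        if p_sw < alpha:
            h, p = kruskal_wallis(*groups)
            rows.append({"dv": dv, "shapiro_p": p_sw, "test": "kruskal_wallis",
                         "statistic": h, "p": p})
        else:
            f, p = sps.f_oneway(*groups)
            rows.append({"dv": dv, "shapiro_p": p_sw, "test": "anova",
                         "statistic": float(f), "p": float(p)})
    return pd.DataFrame(rows).set_index("dv")


# ---------------------------------------------------------------------------
# logistic discrimination
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z: np.ndarray
    p: np.ndarray
    deviance: float
    null_deviance: float
    aic: float
    mcfadden_r2: float
    chi2: float
    chi2_df: int
    chi2_p: float
    converged: bool = True
    separation_flag: bool = False
    fitted: np.ndarray | None = None

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


def logistic_fit(y, predictors: pd.DataFrame | np.ndarray,
                 covariates: pd.DataFrame | None = None) -> LogisticFit:
    """Binomial logistic regression by IRLS (paralyzed side = 1).

    Reports deviance, AIC, McFadden R-squared and the overall model
    chi-square (null deviance minus residual deviance, df = number of
    non-intercept terms) plus per-term Wald z tests.  Quasi-separated fits
    are returned with ``separation_flag`` set rather than raising.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidArgumentError("y must be binary 0/1")
    if y.min() == y.max():
        raise InvalidArgumentError("y is degenerate (single class)")

    if isinstance(predictors, np.ndarray):
        predictors = pd.DataFrame(
            np.atleast_2d(predictors.T).T,
            columns=[f"x{i + 1}" for i in range(np.atleast_2d(predictors.T).T.shape[1])])
    X = predictors.reset_index(drop=True).astype(float)
    if covariates is not None:
        X = pd.concat([X, _encode(covariates.reset_index(drop=True),
                                  list(covariates.columns))], axis=1)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise RankDeficiencyError("collinear design matrix")

    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    import warnings
    separation = False
    with warnings.catch_warnings(record=True) as caught, \
            np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        warnings.simplefilter("always")
        fit = model.fit(maxiter=200)
        null = sm.GLM(y, np.ones((y.size, 1)),
                      family=sm.families.Binomial()).fit()
        for w in caught:
            if "separat" in str(w.message).lower() or "converge" in str(w.message).lower():
                separation = True
        # lazy statsmodels attributes (llf, bse, fittedvalues) are realized
        # here so the numpy error-state guard covers them too
        n_terms = Xc.shape[1] - 1
        chi2 = float(null.deviance - fit.deviance)
        result = LogisticFit(
            terms=list(Xc.columns),
            coefficients=fit.params.to_numpy(),
            standard_errors=fit.bse.to_numpy(),
            z=fit.tvalues.to_numpy(),
            p=fit.pvalues.to_numpy(),
            deviance=float(fit.deviance),
            null_deviance=float(null.deviance),
            aic=float(fit.deviance + 2 * Xc.shape[1]),
            mcfadden_r2=float(1.0 - fit.llf / null.llf),
            chi2=chi2,
            chi2_df=n_terms,
            chi2_p=float(sps.chi2.sf(chi2, n_terms)) if n_terms else float("nan"),
            converged=bool(fit.converged),
            fitted=np.asarray(fit.fittedvalues),
        )
    if np.abs(result.coefficients).max() > 1e3:
        separation = True
    result.separation_flag = separation
    return result


# ---------------------------------------------------------------------------
# ROC / Youden cutoffs
# ---------------------------------------------------------------------------

def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1 (fractions in [0,1])."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise InvalidArgumentError(f"{name} must lie in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    cutoff_youden: float
    auc: float
    auc_se: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden,
        })


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == PARALYZED).astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise InvalidArgumentError(f"labels must be 0/1 or side strings, got {uniq}")
    return arr.astype(int)


def roc_analysis(scores, labels,
                 direction: str = "ge_predicts_paralyzed") -> RocResult:
    """ROC sweep with a fixed direction: score >= threshold -> paralyzed.

    Thresholds are the observed score values.  The cutoff maximizes
    Youden's J (ties broken toward the lowest threshold); the AUC is the
    trapezoidal area over the fixed orientation, so discriminators on which
    the paralyzed side scores lower yield AUC < 0.5 as reported.  The
    orientation is deliberately not auto-flipped; ``direction`` exists so a
    caller cannot silently assume otherwise.
    """
    if direction != "ge_predicts_paralyzed":
        raise InvalidArgumentError(
            "only the fixed direction 'ge_predicts_paralyzed' is supported")
    scores = np.asarray(scores, dtype=float)
    ybin = _as_binary_labels(labels)
    n_pos = int(ybin.sum())
    n_neg = int(ybin.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("both classes must be present")

    thresholds = np.unique(scores)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called_pos = scores >= t
        sens[i] = np.sum(called_pos & (ybin == 1)) / n_pos
        spec[i] = np.sum(~called_pos & (ybin == 0)) / n_neg
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # thresholds ascending

    # trapezoid over the fixed-direction curve: sweeping the threshold down
    # from above the maximum traces (0,0) -> (1,1) in the (FPR, TPR) plane
    fpr = np.concatenate(([0.0], (1.0 - spec)[::-1]))
    tpr = np.concatenate(([0.0], sens[::-1]))
    auc = float(np.trapezoid(tpr, fpr))

    se = _delong_auc_se(scores, ybin)
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, youden=j,
        cutoff=float(thresholds[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
        cutoff_youden=float(j[best]),
        auc=auc, auc_se=se,
    )


# ---------------------------------------------------------------------------
# DeLong AUC machinery
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, ybin: np.ndarray):
    """Placement values (structural components) of the AUC estimator."""
    pos = scores[ybin == 1]
    neg = scores[ybin == 0]
    # V10[i]: fraction of negatives below positive i (ties half credit)
    v10 = np.array([(np.sum(neg < s) + 0.5 * np.sum(neg == s)) / neg.size
                    for s in pos])
    v01 = np.array([(np.sum(pos > s) + 0.5 * np.sum(pos == s)) / pos.size
                    for s in neg])
    return v10, v01


def _delong_auc_se(scores: np.ndarray, ybin: np.ndarray) -> float:
    v10, v01 = _placements(scores, ybin)
    if v10.size < 2 or v01.size < 2:
        return float("nan")
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return float(np.sqrt(var))


def delong_auc_test(scores_a, scores_b, labels,
                    ) -> tuple[float, float, float, float, float]:
    """DeLong test for two correlated AUCs measured on the same trials.

    Returns (auc_a, auc_b, var_diff, z, p) with a two-sided p-value from
    the placement-value covariance estimate.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    ybin = _as_binary_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != ybin.shape:
        raise InvalidArgumentError("paired scores must align with labels")
    if ybin.sum() in (0, ybin.size):
        raise InvalidArgumentError("both classes must be present")

    v10a, v01a = _placements(scores_a, ybin)
    v10b, v01b = _placements(scores_b, ybin)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if np.allclose(scores_a, scores_b):
        return auc_a, auc_b, float(var), 0.0, 1.0
    if var <= 0 or not np.isfinite(var):
        raise UndefinedStatisticError("degenerate variance in DeLong test")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(var), float(z), float(p)


# ---------------------------------------------------------------------------
# exact binomial power / sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Exact one-sample binomial test design (difference from a constant)."""

    p0: float = 0.5
    g: float = 0.4
    alpha: float = 0.05
    power: float = 0.8
    sidedness: str = "one-sided"

    def __post_init__(self):
        if not 0 < self.p0 < 1 or not 0 < self.alpha < 1:
            raise InvalidArgumentError("p0 and alpha must lie in (0, 1)")
        if not 0 <= self.p0 + self.g <= 1:
            raise InvalidArgumentError("p0 + g must lie in [0, 1]")


def binomial_min_n(spec: PowerSpec, n_max: int = 10_000,
                   ) -> tuple[int, int, float]:
    """Smallest n whose exact one-sided binomial test reaches target power.

    For each n the smallest critical count c with exact size
    P(X >= c | p0) <= alpha is found; the first n whose exact power
    P(X >= c | p0 + g) meets the target is returned along with c and the
    achieved power.
    """
    if spec.g == 0:
        raise NoSolutionError("zero effect size: target power is unreachable")
    if spec.sidedness not in ("one-sided", "two-sided"):
        raise InvalidArgumentError("sidedness must be 'one-sided' or 'two-sided'")
    alpha = spec.alpha / 2 if spec.sidedness == "two-sided" else spec.alpha
    p1 = spec.p0 + spec.g
    for n in range(1, n_max + 1):
        # smallest c with upper-tail size <= alpha
        tail = sps.binom.sf(np.arange(n + 1) - 1, n, spec.p0)  # P(X >= c)
        ok = np.flatnonzero(tail <= alpha)
        if ok.size == 0:
            continue
        c = int(ok[0])
        achieved = float(sps.binom.sf(c - 1, n, p1))
        if achieved >= spec.power:
            return n, c, achieved
    raise NoSolutionError(f"no n <= {n_max} reaches power {spec.power}")


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------

def descriptives(table: pd.DataFrame, columns: list[str],
                 factor: str = "side") -> pd.DataFrame:
    """Mean / SD / Min / Max per side for each feature (pooled trials)."""
    rows = []
    for level, grp in table.groupby(factor, observed=True):
        for col in columns:
            x = grp[col].to_numpy(dtype=float)
            rows.append({factor: level, "feature": col,
                         "mean": x.mean(), "sd": x.std(ddof=1),
                         "min": x.min(), "max": x.max(), "n": x.size})
    return pd.DataFrame(rows)
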