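"""Group comparisons, correlation, and the standardized logistic prognosis model.

Skewed or ordinal measures (reported as median + IQR) are compared with the
Mann-Whitney U test, approximately normal measures (mean +/- SD) with
Student's t, and the sex split with chi-squared.  Associations use Spearman's
rho.  The prognosis model is a binomial logistic regression on standardized
predictors with Wald 95% CIs, preceded by a Box-Tidwell linearity-in-the-logit
check (x * ln x interaction terms); classification is summarized by in-sample
sensitivity and specificity at a 0.5 probability cutoff with relapse as the
positive class.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

__all__ = [
    "GroupComparisonResult",
    "LogisticModelResult",
    "Standardizer",
    "mann_whitney_u",
    "u_null_pmf",
    "spearman_rho",
    "standardize",
    "box_tidwell_check",
    "logistic_fit",
    "run_group_analysis",
]


@dataclass
class GroupComparisonResult:
    variable: str
    test: str  # mann_whitney_u | student_t | chi_squared
    statistic: float
    p_value: float
    summary_a: str
    summary_b: str


@dataclass
class Standardizer:
    """Column-wise z-scoring (ddof=1) with stored means/SDs for reuse and inversion."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Standardizer":
        sds = X.std(ddof=1)
        zero = sds[sds <= 0]
        if len(zero):
            raise ValueError(f"zero-variance column(s): {list(zero.index)}")
        return cls(means=X.mean(), sds=sds)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.means) / self.sds

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sds + self.means


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score every column (sample SD, ddof=1); returns the transform for reuse."""
    st = Standardizer.fit(X)
    return st.transform(X), st


@dataclass
class LogisticModelResult:
    table: pd.DataFrame  # index = predictor; coef, odds_ratio, ci_low, ci_high, p_value
    sensitivity: float
    specificity: float
    confusion: dict[str, int]  # tp, fn, tn, fp (relapse = positive)
    separation: bool
    converged: bool
    standardizer: Standardizer
    box_tidwell: pd.Series | None = None
    box_tidwell_verdict: str | None = None


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (min(U_x, U_y), p).

    Exact p when the combined sample is <= 20 and tie-free, otherwise the
    normal approximation with tie correction.  Fully tied data (every value
    identical across both groups) yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across groups; U test degenerate", stacklevel=2)
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_min = min(u_x, len(x) * len(y) - u_x)
    return u_min, float(res.pvalue)


def u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null PMF of the Mann-Whitney U statistic (no ties).

    Dynamic program over the count of rank configurations:
    c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).  Index u runs 0..n1*n2.
    """
    max_u = n1 * n2
    # counts[i][j] = array over u of configurations with i x's and j y's
    counts = [[None] * (n2 + 1) for _ in range(n1 + 1)]
    for j in range(n2 + 1):
        counts[0][j] = np.array([1.0])
    for i in range(1, n1 + 1):
        counts[i][0] = np.array([1.0])
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1)
            prev = counts[i - 1][j]
            a[j : j + len(prev)] += prev
            prev2 = counts[i][j - 1]
            a[: len(prev2)] += prev2
            counts[i][j] = a
    pmf = counts[n1][n2]
    out = np.zeros(max_u + 1)
    out[: len(pmf)] = pmf
    return out / out.sum()


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p; constant input -> (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("paired samples with n >= 4 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = sstats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# logistic prognosis model
# ---------------------------------------------------------------------------

def box_tidwell_check(X: pd.DataFrame, y, alpha: float = 0.05) -> tuple[pd.Series, str]:
    """Linearity-in-the-logit check: add x*ln(x) terms and report their Wald p-values.

    Columns are shifted by 1 - min when not strictly positive.  Verdict is
    "linear" when every interaction p exceeds ``alpha``; if the augmented
    model separates or fails to converge the verdict is "undetermined".
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    shifted = X.copy()
    for col in shifted:
        mn = shifted[col].min()
        if mn <= 0:
            shifted[col] = shifted[col] + (1.0 - mn)
    aug = shifted.copy()
    inter_cols = []
    for col in shifted:
        name = f"{col}_x_lnx"
        aug[name] = shifted[col] * np.log(shifted[col])
        inter_cols.append(name)
    design = sm.add_constant(aug)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        # x and x*ln(x) are near-collinear, so large coefficients are normal here;
        # only non-convergence or unstable Wald SEs mark the check undetermined
        if not fit.mle_retvals.get("converged", False) or not np.all(np.isfinite(fit.bse)):
            return pd.Series(np.nan, index=X.columns), "undetermined"
        pvals = pd.Series(
            [fit.pvalues[name] for name in inter_cols], index=X.columns, dtype=float
        )
        if not np.all(np.isfinite(pvals)):
            return pd.Series(np.nan, index=X.columns), "undetermined"
    except Exception:
        return pd.Series(np.nan, index=X.columns), "undetermined"
    verdict = "linear" if bool((pvals > alpha).all()) else "nonlinear"
    return pvals, verdict


def logistic_fit(
    X: pd.DataFrame,
    y,
    run_box_tidwell: bool = True,
    cutoff: float = 0.5,
) -> LogisticModelResult:
    """Standardized binomial logistic regression predicting relapse (y=1).

    Predictors are z-scored before fitting, so odds ratios are per SD.  Wald
    95% CIs; in-sample sensitivity/specificity at the probability ``cutoff``.
    Perfect separation is flagged and CIs reported unbounded.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    Z, st = standardize(X)
    design = sm.add_constant(Z)

    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception:
            # separated / singular likelihood: fall back to a lightly ridged GLM
            # so predicted classes and coefficient signs are still reportable
            separation = True
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
    params = pd.Series(np.asarray(fit.params), index=design.columns)
    if np.any(np.abs(params.drop("const")) > 15):
        separation = True

    if separation or not converged:
        se = pd.Series(np.inf, index=design.columns)
        pvals = pd.Series(np.nan, index=design.columns)
    else:
        se = pd.Series(np.asarray(fit.bse), index=design.columns)
        pvals = pd.Series(np.asarray(fit.pvalues), index=design.columns)

    zcrit = sstats.norm.ppf(0.975)
    rows = []
    for col in X.columns:
        b = params[col]
        rows.append(
            dict(
                predictor=col,
                coef=b,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - zcrit * se[col])),
                ci_high=float(np.exp(b + zcrit * se[col])),
                p_value=float(pvals[col]),
            )
        )
    table = pd.DataFrame(rows).set_index("predictor")

    prob = np.asarray(fit.predict(design))
    pred = (prob >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")

    bt_p, bt_verdict = (None, None)
    if run_box_tidwell:
        bt_p, bt_verdict = box_tidwell_check(X, y)

    return LogisticModelResult(
        table=table,
        sensitivity=sens,
        specificity=spec,
        confusion=dict(tp=tp, fn=fn, tn=tn, fp=fp),
        separation=separation,
        converged=converged,
        standardizer=st,
        box_tidwell=bt_p,
        box_tidwell_verdict=bt_verdict,
    )


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

#: variable -> test assignment; "u" mirrors median+IQR reporting, "t" mean+/-SD
DEMOGRAPHIC_TESTS: dict[str, str] = {
    "age": "t",
    "sex": "chi2",
    "age_first_drink": "u",
    "age_onset": "u",
    "duration_illness": "u",
    "drinking_days": "u",
    "daily_alcohol": "t",
    "handedness": "u",
    "education": "u",
    "sighd17": "u",
    "bdi_ii": "u",
    "arrs_sv": "t",
    "bis_11": "t",
    "audit": "t",
}

BEHAVIOR_VARS = [
    "fa_rate_emotional",
    "omission_rate_emotional",
    "rt_emotional_ms",
    "rt_nonemotional_ms",
    "vft_words",
    "nback1_pct",
    "nback1_rt_ms",
    "nback2_pct",
    "nback2_rt_ms",
]

REGION_CONTRAST_VARS = ["contrast_frontopolar", "contrast_left_frontotemporal",
                        "contrast_right_frontotemporal"]
VFT_REGION_VARS = ["vft_frontopolar", "vft_left_frontotemporal", "vft_right_frontotemporal"]
RISK_VARS = ["lambda", "gamma"]

LOGISTIC_PREDICTORS = ["contrast_right_frontotemporal", "lambda", "age_onset",
                       "audit", "arrs_sv", "age"]

CORRELATION_CLINICAL_VARS = ["arrs_sv", "age_onset", "daily_alcohol", "bdi_ii",
                             "bis_11", "audit"]


def _summary(vals: np.ndarray, style: str) -> str:
    if style == "t":
        return f"{np.mean(vals):.2f} ± {np.std(vals, ddof=1):.2f}"
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return f"{med:.2f} ({q25:.2f}–{q75:.2f})"


def _compare(name: str, a: np.ndarray, b: np.ndarray, test: str) -> GroupComparisonResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "t":
        stat, p = sstats.ttest_ind(a, b)
        return GroupComparisonResult(name, "student_t", float(stat), float(p),
                                     _summary(a, "t"), _summary(b, "t"))
    u, p = mann_whitney_u(a, b)
    return GroupComparisonResult(name, "mann_whitney_u", u, p,
                                 _summary(a, "u"), _summary(b, "u"))


def _chi2_sex(cohort: pd.DataFrame) -> GroupComparisonResult:
    tab = pd.crosstab(cohort["group"], cohort["sex"])
    chi2, p, _, _ = sstats.chi2_contingency(tab)
    summaries = {
        g: "/".join(str(int(tab.loc[g].get(s, 0))) for s in ("M", "F"))
        for g in tab.index
    }
    return GroupComparisonResult("sex", "chi_squared", float(chi2), float(p),
                                 summaries.get("abstainer", ""), summaries.get("relapser", ""))


def _comparison_table(cohort: pd.DataFrame, variables: list[str],
                      tests: dict[str, str] | None = None) -> pd.DataFrame:
    abst = cohort[cohort["group"] == "abstainer"]
    rel = cohort[cohort["group"] == "relapser"]
    rows = []
    for var in variables:
        if var == "sex":
            res = _chi2_sex(cohort)
        else:
            if var not in cohort.columns:
                continue
            a = abst[var].dropna().to_numpy()
            b = rel[var].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0:
                continue
            test = (tests or {}).get(var, "u")
            res = _compare(var, a, b, test)
        rows.append(dict(variable=res.variable, abstainers=res.summary_a,
                         relapsers=res.summary_b, test=res.test,
                         statistic=res.statistic, p_value=res.p_value))
    return pd.DataFrame(rows)


def run_group_analysis(cohort: pd.DataFrame) -> dict:
    """Full group-level report from a one-row-per-subject cohort table.

    Returns a dict of DataFrames (demographics, behavior, region contrasts,
    vft activation, risk parameters, correlations, logistic model) plus a
    flat ``summary`` dict of headline numbers.  Variables absent from the
    cohort are skipped.
    """
    report: dict = {}
    report["demographics"] = _comparison_table(
        cohort, list(DEMOGRAPHIC_TESTS), DEMOGRAPHIC_TESTS
    )
    report["behavior"] = _comparison_table(cohort, BEHAVIOR_VARS)
    report["region_contrasts"] = _comparison_table(cohort, REGION_CONTRAST_VARS)
    report["vft_activation"] = _comparison_table(cohort, VFT_REGION_VARS)
    report["risk_params"] = _comparison_table(cohort, RISK_VARS)

    corr_rows = []
    for grp in ("abstainer", "relapser"):
        sub = cohort[cohort["group"] == grp]
        for var in CORRELATION_CLINICAL_VARS:
            if var not in sub.columns or "contrast_right_frontotemporal" not in sub.columns:
                continue
            pair = sub[["contrast_right_frontotemporal", var]].dropna()
            if len(pair) < 4:
                continue
            rho, p = spearman_rho(pair["contrast_right_frontotemporal"], pair[var])
            corr_rows.append(dict(group=grp, variable=var, rho=rho, p_value=p))
    report["correlations"] = pd.DataFrame(corr_rows)

    predictors = [p for p in LOGISTIC_PREDICTORS if p in cohort.columns]
    model_df = cohort[predictors + ["relapse"]].dropna()
    logit = None
    if len(predictors) >= 1 and model_df["relapse"].nunique() == 2:
        logit = logistic_fit(model_df[predictors], model_df["relapse"])
        report["logistic_table"] = logit.table.reset_index()
    report["logistic"] = logit

    summary: dict = {"n_abstainers": int((cohort["group"] == "abstainer").sum()),
                     "n_relapsers": int((cohort["group"] == "relapser").sum())}

    def _grab(df: pd.DataFrame, var: str, key: str) -> None:
        row = df[df["variable"] == var]
        if len(row):
            summary[key + "_p"] = float(row["p_value"].iloc[0])
            summary[key + "_stat"] = float(row["statistic"].iloc[0])

    _grab(report["risk_params"], "lambda", "lambda")
    _grab(report["risk_params"], "gamma", "gamma")
    _grab(report["region_contrasts"], "contrast_right_frontotemporal", "rft_contrast")
    _grab(report["behavior"], "rt_nonemotional_ms", "rt_nonemotional")
    _grab(report["behavior"], "nback2_pct", "nback2_pct")

    for grp in ("abstainer", "relapser"):
        sub = cohort[cohort["group"] == grp]
        for var, key in (("lambda", f"{grp}_lambda_median"),
                         ("contrast_right_frontotemporal", f"{grp}_rft_contrast_median"),
                         ("rt_nonemotional_ms", f"{grp}_rt_nonemotional_median")):
            if var in sub.columns:
                summary[key] = float(sub[var].median())
    if logit is not None:
        summary["sensitivity_pct"] = 100.0 * logit.sensitivity
        summary["specificity_pct"] = 100.0 * logit.specificity
        for pred in logit.table.index:
            summary[f"or_{pred}"] = float(logit.table.loc[pred, "odds_ratio"])
        if logit.box_tidwell_verdict is not None:
            summary["box_tidwell_verdict"] = logit.box_tidwell_verdict
    if len(report["correlations"]):
        arrs = report["correlations"].query(
            "group == 'abstainer' and variable == 'arrs_sv'"
        )
        if len(arrs):
            summary["abstainer_arrs_rho"] = float(arrs["rho"].iloc[0])
            summary["abstainer_arrs_p"] = float(arrs["p_value"].iloc[0])
    report["summary"] = summary
    return report
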