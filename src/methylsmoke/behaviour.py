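"""Smoking-behaviour derivations, power, and score-behaviour regressions.

Covers the cumulative-dose derivation (pack years), the a-priori power of
a two-sample comparison of group mean methylation at a stringent
(Bonferroni) significance level, and linear models relating the weighted
methylation smoking score to behavioural measures (cigarettes per day,
pack years) with an ethnic-group interaction and, where the interaction
is significant at 0.05, ethnicity-stratified slopes with 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pack_years", "years_smoked", "two_sample_power",
    "score_behaviour_regression", "RegressionResult", "GroupFit",
]


def pack_years(cigarettes_per_day, years_smoked):
    """Cumulative dose: (cigarettes per day / 20) * years smoked."""
    cpd = np.asarray(cigarettes_per_day, dtype=float)
    yrs = np.asarray(years_smoked, dtype=float)
    if np.any(cpd[np.isfinite(cpd)] < 0) or np.any(yrs[np.isfinite(yrs)] < 0):
        raise ValueError("cigarettes per day and years smoked must be non-negative")
    out = (cpd / 20.0) * yrs
    return float(out) if out.ndim == 0 else out


def years_smoked(sheet: pd.DataFrame) -> pd.Series:
    """Years of smoking implied by a sample sheet.

    Current smokers: age - age started. Former smokers: age - age started
    - years since quitting. Never smokers: NaN.
    """
    yrs = sheet["age_years"] - sheet["age_started_years"]
    former = sheet["smoking_status"] == "former"
    yrs = yrs.where(~former, yrs - sheet["years_since_quitting"])
    return yrs.clip(lower=0.0)


def two_sample_power(delta: float, sd: float, n1: int, n2: int, alpha: float,
                     method: str = "nct") -> float:
    """Power of a two-sided two-sample comparison of means.

    Parameters
    ----------
    delta : true absolute difference in group means (same units as sd).
    sd : common within-group standard deviation.
    n1, n2 : group sizes.
    alpha : two-sided significance level (may be a Bonferroni threshold).
    method : "nct" for exact noncentral-t power of the pooled t-test,
        "normal" for the normal approximation (z-test power).

    Returns the power as a fraction in [0, 1].
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ncp = (delta / sd) / np.sqrt(1.0 / n1 + 1.0 / n2)
    if method == "normal":
        z = stats.norm.isf(alpha / 2.0)
        return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))
    if method == "nct":
        df = n1 + n2 - 2
        tcrit = stats.t.isf(alpha / 2.0, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        # scipy's nct can return nan in the far (negligible) tail
        return float(np.nan_to_num(upper) + np.nan_to_num(lower))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GroupFit:
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int


@dataclass
class RegressionResult:
    """Pooled and (optionally) ethnicity-stratified regression output."""

    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    interaction_p: float | None = None
    by_group: dict = field(default_factory=dict)


def _ols_fit(x: np.ndarray, y: np.ndarray) -> GroupFit:
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int()[1]
    return GroupFit(float(fit.params[1]), float(lo), float(hi),
                    float(fit.pvalues[1]), float(fit.rsquared), len(y))


def score_behaviour_regression(scores, behaviour, ethnicity,
                               min_stratum: int = 4) -> RegressionResult:
    """Regress a behavioural measure on smoking score, testing ethnicity.

    Fits behaviour ~ score * ethnic_group; reports the pooled slope (95%
    CI, p, R^2) and the interaction p-value. When the interaction is
    significant at 0.05, ethnicity-stratified slopes are fitted as well;
    a stratum with fewer than ``min_stratum`` complete observations is
    refused (recorded as None, with a warning).

    Rows with missing behaviour (e.g. never smokers, for whom dose
    variables are undefined) are dropped.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "behaviour": np.asarray(behaviour, dtype=float),
        "ethnicity": np.asarray(ethnicity),
    }).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 complete observations")

    pooled = _ols_fit(df["score"].values, df["behaviour"].values)

    interaction_p = None
    groups = df["ethnicity"].unique()
    if len(groups) >= 2:
        eth_d = pd.get_dummies(df["ethnicity"], drop_first=True, dtype=float)
        X = np.column_stack([df["score"].values, eth_d.values,
                             eth_d.values * df["score"].values[:, None]])
        fit_full = sm.OLS(df["behaviour"].values, sm.add_constant(X)).fit()
        k = eth_d.shape[1]
        # F-test on the score x ethnicity columns (the last k regressors)
        R = np.zeros((k, fit_full.params.shape[0]))
        for i in range(k):
            R[i, -(k - i)] = 1.0
        interaction_p = float(fit_full.f_test(R).pvalue)

    result = RegressionResult(
        slope=pooled.slope, ci_low=pooled.ci_low, ci_high=pooled.ci_high,
        p_value=pooled.p_value, r_squared=pooled.r_squared,
        interaction_p=interaction_p,
    )
    if interaction_p is not None and interaction_p < 0.05:
        for g in groups:
            sub = df[df["ethnicity"] == g]
            if len(sub) < min_stratum:
                warnings.warn(f"stratum {g!r} has n={len(sub)} < {min_stratum}; "
                              "stratified fit refused", stacklevel=2)
                result.by_group[g] = None
                continue
            result.by_group[g] = _ols_fit(sub["score"].values, sub["behaviour"].values)
    return result
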