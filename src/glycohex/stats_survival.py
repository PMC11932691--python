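"""Statistical machinery: correlation, group tests, AUC, outliers, survival.

Thin, contract-checked wrappers around scipy and lifelines with the exact
conventions used throughout the pipeline made explicit:

* Pearson correlation significance from the t distribution with n-2 df
  (two-sided), pairwise-complete over missing values.
* Unpaired two-sided t tests (Student by default, Welch optional).
* One-way ANOVA with Tukey HSD adjustment for pairwise contrasts.
* Mann-Whitney AUC, P(pos > neg) + 0.5 P(tie), computed from ranks.
* Robust outlier flagging by median +/- k*MAD (k = 5 by default) as a
  documented, open replacement for the proprietary ROUT procedure; flagged
  indices are reported, never silently removed.
* Kaplan-Meier product-limit estimation, two-group log-rank test and Cox
  proportional-hazards fits (Newton-Raphson partial likelihood, Efron tie
  handling) via lifelines.
* Percentile dichotomization with the linear-interpolation quantile
  convention; values strictly above the threshold are "high".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "PearsonResult",
    "TTestResult",
    "AnovaResult",
    "CoxFit",
    "pearson",
    "pearson_p_from_r",
    "ttest",
    "anova_tukey",
    "auc",
    "flag_outliers",
    "km_estimate",
    "logrank",
    "dichotomize_percentile",
    "cox_fit",
]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame  # columns: group_a, group_b, mean_diff, p_adj


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate coefficients of a proportional-hazards fit.

    ``summary`` has one row per covariate with columns
    ``coef, hr, hr_ci_low, hr_ci_high, se, p``; Wald 95% CIs are
    exp(coef +/- 1.96 se).
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient at sample size n.

    t = r*sqrt(n-2)/sqrt(1-r^2) referred to the t distribution with n-2 df.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if not -1 < r < 1:
        return 0.0
    t = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(t, df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with t-distribution significance test.

    t = r*sqrt(n-2)/sqrt(1-r^2), two-sided p from the t distribution with
    n-2 degrees of freedom. Missing values are dropped pairwise.
    """
    xv, yv = _pairwise_complete(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"pearson requires at least 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return PearsonResult(r=r, t=math.inf if r > 0 else -math.inf, p=0.0, n=n)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return PearsonResult(r=r, t=t, p=pearson_p_from_r(r, n), n=n)


def ttest(group_a: Sequence[float], group_b: Sequence[float], welch: bool = False) -> TTestResult:
    """Unpaired two-sided two-sample t test (Student; Welch if requested)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise comparisons."""
    if len(groups) < 2:
        raise ValueError("anova requires at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    for k, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaResult(f=float(f), p=float(p), tukey=pd.DataFrame(rows))


def auc(group_pos: Sequence[float], group_neg: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg), from ranks."""
    pos = np.asarray(group_pos, dtype=float)
    neg = np.asarray(group_neg, dtype=float)
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc requires non-empty groups")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


def flag_outliers(x: Sequence[float], k: float = 5.0) -> np.ndarray:
    """Indices of points outside median +/- k*MAD (scaled MAD, normal-consistent).

    With MAD == 0 (e.g. constant input) nothing is flagged. Flagging is a
    report; callers decide whether to exclude.
    """
    xv = np.asarray(x, dtype=float)
    med = np.nanmedian(xv)
    mad = np.nanmedian(np.abs(xv - med)) * 1.4826
    if mad == 0 or not np.isfinite(mad):
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(xv - med) > k * mad)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a frame indexed by event time with columns ``n_risk``,
    ``n_events`` and ``survival`` (S(0) = 1, nonincreasing).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("follow-up times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "n_risk": table["at_risk"].astype(int),
            "n_events": table["observed"].astype(int),
            "survival": kmf.survival_function_["KM_estimate"].reindex(table.index).values,
        },
        index=table.index.rename("time"),
    )
    return out


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p)."""
    res = _ll_logrank(
        np.asarray(times_a, float),
        np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, int),
        event_observed_B=np.asarray(events_b, int),
    )
    return float(res.test_statistic), float(res.p_value)


def dichotomize_percentile(
    values: Sequence[float], q: float = 0.75
) -> tuple[np.ndarray, float]:
    """Split values at the empirical q-quantile (linear interpolation).

    Values strictly above the threshold are labeled ``"high"``, the rest
    ``"low"``. Returns (labels, threshold). All-equal input raises (no
    split exists).
    """
    v = np.asarray(values, dtype=float)
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if np.ptp(v[np.isfinite(v)]) == 0:
        raise ValueError("cannot dichotomize: all values equal")
    threshold = float(np.nanquantile(v, q))
    labels = np.where(v > threshold, "high", "low")
    return labels, threshold


def cox_fit(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit over the given covariates.

    Maximizes the Efron partial likelihood by Newton-Raphson (lifelines);
    Wald 95% CIs on the hazard-ratio scale. Constant covariates and
    event-free cohorts are rejected up front.
    """
    covariates = list(covariates)
    df = cohort[[duration_col, event_col, *covariates]].dropna()
    if int(df[event_col].sum()) < 1:
        raise ValueError("cox_fit requires at least one observed event")
    for c in covariates:
        if np.ptp(df[c].to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_ci_low": s["exp(coef) lower 95%"],
            "hr_ci_high": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df[event_col].sum()),
    )
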