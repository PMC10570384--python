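"""Group-comparison statistics and behaviour-activity regressions.

All tests are two-tailed and no multiple-comparison correction is
applied by default (a Benjamini-Hochberg helper is available for users
who want one). The rank-sum statistic is reported as the sum of ranks of
the first group, with midranks for ties — the convention the comparison
tables print.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "BehaviorCorrelation",
    "compare_groups",
    "anova_oneway",
    "BehaviorRegression",
    "correlate_behavior",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int | None = None
    paired: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value out of [0,1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "paired": self.paired,
        }


_MIN_N = {"ranksum": 3, "t2": 2, "paired_t": 2}


def compare_groups(
    values_a,
    values_b,
    test: str = "ranksum",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-tailed two-group comparison.

    ``ranksum``: Wilcoxon rank-sum; the statistic is the sum of the ranks
    of group A in the pooled sample (W = U_A + n_A(n_A+1)/2), with an
    exact p-value for small tie-free samples. ``t2``: two-sample t
    (Student by default, Welch with ``equal_var=False``). ``paired_t``:
    paired t on equal-length samples. Degenerate zero-variance inputs
    with equal means report statistic 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test not in _MIN_N:
        raise ValueError(f"unknown test {test!r}")
    lo = _MIN_N[test]
    if a.size < lo or b.size < lo:
        raise ValueError(f"{test} requires at least {lo} values per group")

    if test == "ranksum":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        w = float(res.statistic + a.size * (a.size + 1) / 2.0)
        return ComparisonResult("ranksum", w, float(res.pvalue), a.size, b.size)

    if test == "t2":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return ComparisonResult("t2", 0.0, 1.0, a.size, b.size)
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return ComparisonResult("t2", float(res.statistic), float(res.pvalue), a.size, b.size)

    # paired t
    if a.size != b.size:
        raise ValueError("paired test requires equal-length samples")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return ComparisonResult("paired_t", 0.0, 1.0, a.size, b.size, paired=True)
        # constant nonzero difference: zero variance, infinite t
        return ComparisonResult(
            "paired_t", float(np.sign(d[0]) * np.inf), 0.0, a.size, b.size, paired=True
        )
    res = sps.ttest_rel(a, b)
    return ComparisonResult("paired_t", float(res.statistic), float(res.pvalue),
                            a.size, b.size, paired=True)


def anova_oneway(groups) -> ComparisonResult:
    """One-way ANOVA across 2+ groups (F and two-tailed p).

    When every observation is identical (zero between- and within-group
    variance) the comparison is vacuous and F = 0, p = 1 is reported.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("one-way ANOVA requires >=2 groups with >=2 values each")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0 and ss_between == 0:
        return ComparisonResult("anova_oneway", 0.0, 1.0, allv.size)
    f, p = sps.f_oneway(*arrs)
    return ComparisonResult("anova_oneway", float(f), float(p), allv.size)


@dataclass(frozen=True)
class BehaviorCorrelation:
    """Linear association between a behaviour score and regional activity."""

    region: str | None
    behavior: str | None
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    pvalue: float
    n: int

    def summary(self) -> str:
        return (
            f"Behaviour-activity regression"
            f"{f' ({self.region} vs {self.behavior})' if self.region else ''}\n"
            f"  n = {self.n}\n"
            f"  slope = {self.slope:.4g}, intercept = {self.intercept:.4g}\n"
            f"  R^2 = {self.r_squared:.4f}\n"
            f"  F (vs constant model) = {self.f_statistic:.4g}, p = {self.pvalue:.4g}"
        )


class BehaviorRegression:
    """Model: per-mouse regional activity medians against a behaviour score.

    ``fit()`` runs a simple linear regression of the activity medians on
    the behaviour values and tests the slope against the constant-only
    model (F-test; for one predictor F = t^2 of the slope).
    """

    def __init__(self, activity, behavior, region: str | None = None,
                 behavior_name: str | None = None):
        self.activity = np.asarray(activity, dtype=float)
        self.behavior = np.asarray(behavior, dtype=float)
        if self.activity.shape != self.behavior.shape:
            raise ValueError("activity and behaviour values must pair one-to-one")
        if self.activity.size < 3:
            raise ValueError("need at least 3 mice")
        if np.ptp(self.behavior) == 0:
            raise ValueError("behaviour predictor has zero variance")
        self.region = region
        self.behavior_name = behavior_name

    def fit(self) -> BehaviorCorrelation:
        import statsmodels.api as sm

        X = sm.add_constant(self.behavior)
        res = sm.OLS(self.activity, X).fit()
        return BehaviorCorrelation(
            region=self.region,
            behavior=self.behavior_name,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r_squared=float(res.rsquared),
            f_statistic=float(res.fvalue),
            pvalue=float(res.f_pvalue),
            n=self.activity.size,
        )


def correlate_behavior(activity, behavior, region: str | None = None,
                       behavior_name: str | None = None) -> BehaviorCorrelation:
    """Convenience wrapper: BehaviorRegression(...).fit()."""
    return BehaviorRegression(activity, behavior, region, behavior_name).fit()


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment (off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]


def comparison_report(results: list[ComparisonResult | BehaviorCorrelation]) -> pd.DataFrame:
    """Tabulate a batch of comparison results for CSV export."""
    rows = []
    for r in results:
        if isinstance(r, ComparisonResult):
            rows.append(r.to_dict())
        else:
            rows.append(
                {"test": "behavior_regression", "statistic": r.f_statistic,
                 "pvalue": r.pvalue, "n_a": r.n, "n_b": None, "paired": False}
            )
    return pd.DataFrame(rows)
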