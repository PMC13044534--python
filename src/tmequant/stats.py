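"""Cohort statistics: rank tests, two-way ANOVA, multiplicity adjustment.

Group comparisons use the unpaired two-sided Mann-Whitney test (exact
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise) or the Wilcoxon signed-rank test for
matched samples.  Factorial comparisons (class x site percentages) use
two-way ANOVA with type-II sums of squares — per-sample class percentages
are unbalanced across sites — followed by Šídák or Bonferroni adjustment.
Significance is 0.05 two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "two_way_anova",
    "adjust_p",
]

#: largest combined sample size for exact Mann-Whitney enumeration
EXACT_MW_MAX_N = 12
#: largest sample size for exact Wilcoxon sign-pattern enumeration
EXACT_WILCOXON_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int = 0
    exact: bool = False
    adjustment: str = "none"
    degenerate: bool = False

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not 0.0 <= self.pvalue <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def mann_whitney(a, b) -> TestResult:
    """Unpaired two-sided Mann-Whitney U test.

    Exact enumeration when n_a + n_b <= 12 with no ties across groups,
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= EXACT_MW_MAX_N and not ties
    res = sps.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method="mann_whitney",
        n1=a.size, n2=b.size, exact=exact,
    )


def wilcoxon_signed_rank(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on matched differences.

    Zero differences are dropped; when all are zero the test is degenerate
    and reported with p = 1.  Exact sign-pattern enumeration for n <= 15
    nonzero tie-free differences, else the normal approximation.
    """
    d = np.asarray(paired_diffs, float)
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(
            statistic=0.0, pvalue=1.0, method="wilcoxon_signed_rank",
            n1=d.size, degenerate=True,
        )
    ties = np.unique(np.abs(nz)).size < nz.size
    exact = nz.size <= EXACT_WILCOXON_MAX_N and not ties
    res = sps.wilcoxon(
        nz,
        alternative="two-sided",
        zero_method="wilcox",
        mode="exact" if exact else "approx",
        correction=not exact,
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method="wilcoxon_signed_rank",
        n1=nz.size, exact=exact,
    )


def two_way_anova(values, factor_a, factor_b) -> dict[str, TestResult]:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Returns a TestResult per effect keyed ``factor_a``, ``factor_b`` and
    ``interaction``.  Degenerate designs (all responses equal) are flagged
    with p = 1.  Raises when a factor has a single level.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "fa": np.asarray(factor_a, object),
        "fb": np.asarray(factor_b, object),
    })
    for col in ("fa", "fb"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    if np.allclose(df["value"].var(ddof=0), 0.0):
        out = {}
        for key in ("factor_a", "factor_b", "interaction"):
            out[key] = TestResult(
                statistic=0.0, pvalue=1.0, method="two_way_anova",
                n1=len(df), degenerate=True,
            )
        return out
    model = smf.ols("value ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    keymap = {"C(fa)": "factor_a", "C(fb)": "factor_b",
              "C(fa):C(fb)": "interaction"}
    out = {}
    for row, key in keymap.items():
        out[key] = TestResult(
            statistic=float(table.loc[row, "F"]),
            pvalue=float(table.loc[row, "PR(>F)"]),
            method="two_way_anova",
            n1=len(df),
        )
    return out


def adjust_p(p_values, method: str = "sidak") -> np.ndarray:
    """Multiple-comparison adjustment over m = len(p_values) comparisons.

    Šídák: ``1 - (1 - p)^m``; Bonferroni: ``min(1, m p)``.  Šídák-adjusted
    values never exceed Bonferroni's.
    """
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    raise ValueError(f"unknown adjustment method {method!r}")
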