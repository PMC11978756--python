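"""Group statistics used throughout the pipeline.

Normality gating (Shapiro-Wilk), two-sided Wilcoxon rank-sum tests with
Bonferroni correction, fixed-effects two-way ANOVA (Type-II sums of squares),
Hedge's g effect size, and the 1000x resampling procedure that balances
unequal group sizes by subsampling the larger group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from ._seeding import substream

__all__ = [
    "normality_gate",
    "rank_sum",
    "two_way_anova",
    "hedges_g",
    "resample_balance",
    "GroupComparison",
    "ResampleResult",
]


@dataclass
class GroupComparison:
    """One two-group test: statistic, raw and Bonferroni-adjusted p."""

    test: str
    statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int
    notes: str = ""


def normality_gate(*groups: np.ndarray, alpha: float = 0.05) -> tuple[str, bool]:
    """Choose the test family from per-group Shapiro-Wilk results.

    Returns ("parametric" | "nonparametric", flagged).  Parametric only when
    every group passes Shapiro-Wilk at ``alpha``; groups with n < 3 or
    degenerate (constant) values force nonparametric with a flag.
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3 or np.ptp(g) == 0:
            return "nonparametric", True
        if stats.shapiro(g).pvalue < alpha:
            return "nonparametric", False
    return "parametric", False


def rank_sum(group_a: np.ndarray, group_b: np.ndarray, corrections: int = 1) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test with Bonferroni adjustment.

    Exact p-values are used for small untied samples (scipy's automatic
    method selection), matching exhaustive permutation enumeration there.
    All-tied inputs yield p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if corrections < 1:
        raise ValueError("corrections must be >= 1")
    if np.ptp(np.concatenate([a, b])) == 0:
        stat, p = float(a.size * b.size / 2), 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        test="rank_sum",
        statistic=stat,
        p_value=p,
        p_adjusted=min(1.0, p * corrections),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def two_way_anova(
    values: np.ndarray, factor_a: np.ndarray, factor_b: np.ndarray
) -> pd.DataFrame:
    """Fixed-effects two-factor ANOVA with interaction, Type-II SS.

    Returns a table indexed by factor_a / factor_b / interaction with F and p
    columns.  Each factor needs at least two levels.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "A": np.asarray(factor_a),
        "B": np.asarray(factor_b),
    })
    for col in ("A", "B"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs at least 2 levels")
    fit = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    table = anova_lm(fit, typ=2)
    table = table.rename(index={"C(A)": "factor_a", "C(B)": "factor_b",
                                "C(A):C(B)": "interaction", "Residual": "residual"})
    return table[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})


def hedges_g(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Bias-corrected standardized mean difference (A - B) / pooled SD.

    Applies the small-sample correction J = 1 - 3/(4(nA+nB)-9).  Zero pooled
    SD returns NaN (flagged undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return np.nan
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class ResampleResult:
    """Output of the sample-size-balancing resampling procedure."""

    medians: np.ndarray
    control_median: float
    overlap_probability: float
    n_iter: int = 1000
    notes: str = field(default="two-sided empirical overlap: 2*min(P(med>=ctrl), P(med<=ctrl)), capped at 1")


def resample_balance(
    treated_values: np.ndarray,
    n_control: int,
    control_median: float,
    n_iter: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> ResampleResult:
    """Balance unequal group sizes by subsampling the treated pool.

    Draws ``n_iter`` subsamples of size ``n_control`` from ``treated_values``
    (without replacement by default), records each subsample's median, and
    reports the two-sided probability that the resampled medians overlap the
    control median.
    """
    treated = np.asarray(treated_values, dtype=float)
    if n_control > treated.size and not replace:
        raise ValueError("n_control exceeds the treated sample size")
    rng = substream(seed, "resample-balance")
    medians = np.empty(n_iter)
    for i in range(n_iter):
        medians[i] = np.median(rng.choice(treated, size=n_control, replace=replace))
    ge = float(np.mean(medians >= control_median))
    le = float(np.mean(medians <= control_median))
    overlap = min(1.0, 2.0 * min(ge, le))
    return ResampleResult(
        medians=medians,
        control_median=float(control_median),
        overlap_probability=overlap,
        n_iter=n_iter,
    )
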