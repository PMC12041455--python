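"""Group-comparison statistics for per-subject metric tables.

Covers the tests used for scenario comparisons: Welch's unpaired two-tailed
t-test, Welch and Brown-Forsythe heteroscedastic one-way ANOVAs, two-way
ANOVA (genotype x treatment) with post-hoc Tukey HSD across the four cells,
repeated-measures one-way ANOVA for paired pre/post designs, and ROUT robust
outlier removal at a chosen false-discovery level Q.

ROUT is defined for robust nonlinear regression; comparing group means is a
constant-model fit, so this implementation uses that specialization: a robust
(Lorentzian-loss) location estimate, the robust standard deviation of the
residuals (RSDR, from the 68.27th percentile of |residuals|), and an
FDR-style sweep over the largest residuals at level Q. Outlier removal is an
explicit, opt-in step — nothing in this module removes points silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sst

__all__ = [
    "TestResult",
    "welch_t_test",
    "welch_anova",
    "brown_forsythe",
    "two_way_anova_tukey",
    "rm_one_way_anova",
    "rout_outliers",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float
    direction: float | None = None           # sign of (mean_a - mean_b) where defined
    pairwise: pd.DataFrame | None = None     # Tukey-adjusted contrasts
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0 <= self.pvalue <= 1):
            raise ValueError("p value outside [0, 1]")

    def summary(self) -> str:
        dfs = ", ".join(f"{d:g}" for d in self.df)
        s = f"{self.test}: statistic={self.statistic:.4g}, df=({dfs}), p={self.pvalue:.4g}"
        if self.pairwise is not None:
            s += "\n" + self.pairwise.to_string(index=False)
        return s


def _clean(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float).ravel()
    return a[~np.isnan(a)]


def welch_t_test(a, b) -> TestResult:
    """Unpaired two-tailed t-test with the Welch-Satterthwaite correction."""
    a, b = _clean(a), _clean(b)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, (float(a.size + b.size - 2),), 1.0, 0.0)
        raise ValueError("both groups have zero variance with different means")
    res = sst.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), (float(res.df),),
                      float(res.pvalue), direction=float(np.sign(a.mean() - b.mean())))


def welch_anova(*groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA for >= 3 independent groups."""
    groups = [_clean(g) for g in groups]
    _check_groups(groups)
    df = pd.DataFrame({
        "value": np.concatenate(groups),
        "group": np.repeat([str(i) for i in range(len(groups))],
                           [g.size for g in groups]),
    })
    import pingouin as pg
    out = pg.welch_anova(data=df, dv="value", between="group").iloc[0]
    return TestResult("welch_anova", float(out["F"]),
                      (float(out["ddof1"]), float(out["ddof2"])),
                      float(out["p_unc"]))


def brown_forsythe(*groups) -> TestResult:
    """Brown-Forsythe F* one-way ANOVA for means under unequal variances.

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with Satterthwaite
    denominator degrees of freedom. (This is the test for equality of means,
    not the Levene-type spread test of the same name.)
    """
    groups = [_clean(g) for g in groups]
    _check_groups(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    s2 = np.array([g.var(ddof=1) for g in groups])
    N = n.sum()
    grand = np.concatenate(groups).mean()
    denom_terms = (1 - n / N) * s2
    denom = denom_terms.sum()
    if denom == 0:
        p = 1.0 if np.allclose(m, grand) else 0.0
        return TestResult("brown_forsythe", 0.0 if p == 1.0 else np.inf,
                          (float(len(groups) - 1), np.inf), p)
    F = float((n * (m - grand) ** 2).sum() / denom)
    c = denom_terms / denom
    df2 = float(1.0 / (c**2 / (n - 1)).sum())
    df1 = float(len(groups) - 1)
    return TestResult("brown_forsythe", F, (df1, df2),
                      float(sst.f.sf(F, df1, df2)))


def _check_groups(groups) -> None:
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")


def two_way_anova_tukey(table: pd.DataFrame, value: str = "value",
                        factor_a: str = "genotype",
                        factor_b: str = "treatment") -> dict[str, TestResult]:
    """Two-way ANOVA (type II) on a 2x2 design plus Tukey HSD across the cells.

    Returns results keyed by the two main effects, their interaction, and
    ``"tukey"`` (cell-wise pairwise contrasts; unbalanced cells use the
    Tukey-Kramer adjustment of the HSD).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[value, factor_a, factor_b]].dropna().copy()
    if df.groupby([factor_a, factor_b])[value].count().min() < 2:
        raise ValueError("every cell needs n >= 2")
    model = smf.ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    resid_df = float(aov.loc["Residual", "df"])

    def row(name: str, label: str) -> TestResult:
        r = aov.loc[label]
        return TestResult(name, float(r["F"]), (float(r["df"]), resid_df),
                          float(r["PR(>F)"]))

    cell = df[factor_a].astype(str) + ":" + df[factor_b].astype(str)
    hsd = pairwise_tukeyhsd(df[value].to_numpy(), cell.to_numpy())
    pair = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return {
        factor_a: row(f"anova_{factor_a}", f"C({factor_a})"),
        factor_b: row(f"anova_{factor_b}", f"C({factor_b})"),
        "interaction": row("anova_interaction", f"C({factor_a}):C({factor_b})"),
        "tukey": TestResult("tukey_hsd", float("nan"), (float("nan"),),
                            float(min(pair["p-adj"].astype(float))), pairwise=pair),
    }


def rm_one_way_anova(table: pd.DataFrame, value: str = "value",
                     subject: str = "subject",
                     condition: str = "condition") -> TestResult:
    """Repeated-measures one-way ANOVA for paired pre/post designs.

    Complete cases only: subjects missing any condition are dropped.
    """
    from statsmodels.stats.anova import AnovaRM

    df = table[[value, subject, condition]].dropna()
    n_cond = df[condition].nunique()
    counts = df.groupby(subject)[condition].nunique()
    keep = counts[counts == n_cond].index
    df = df[df[subject].isin(keep)]
    if n_cond < 2 or df[subject].nunique() < 3:
        raise ValueError("need >= 2 conditions and >= 3 complete subjects")
    wide = df.pivot_table(index=subject, columns=condition, values=value)
    if np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]]):
        k = n_cond - 1
        return TestResult("rm_anova", 0.0,
                          (float(k), float(k * (wide.shape[0] - 1))), 1.0)
    res = AnovaRM(df, depvar=value, subject=subject, within=[condition]).fit()
    r = res.anova_table.iloc[0]
    return TestResult("rm_anova", float(r["F Value"]),
                      (float(r["Num DF"]), float(r["Den DF"])), float(r["Pr > F"]))


def _robust_location(x: np.ndarray) -> float:
    """Constant-model robust fit: minimise the Lorentzian merit function."""
    med = float(np.median(x))
    rsdr = _rsdr(x - med, k_params=1)
    if rsdr == 0:
        return med
    for _ in range(3):
        res = optimize.minimize_scalar(
            lambda m: np.log1p(((x - m) / rsdr) ** 2).sum(),
            bracket=(med - rsdr, med, med + rsdr))
        med = float(res.x)
        new = _rsdr(x - med, k_params=1)
        if new == 0:
            break
        rsdr = new
    return med


def _rsdr(residuals: np.ndarray, k_params: int) -> float:
    """Robust SD of residuals: P68.27 of |r|, inflated by N/(N-K)."""
    n = residuals.size
    return float(np.percentile(np.abs(residuals), 68.27) * n / (n - k_params))


def rout_outliers(values, q: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier detection at false-discovery level Q (percent).

    Returns ``(kept, flagged)`` as index arrays into ``values``. Up to 30% of
    the sample (the procedure's cap) is examined, most extreme residual first:
    residual i (rank j among those examined) is an outlier when its two-tailed
    t probability at N-1 df falls below Q/100 x (N - j + 1)/N; all points at
    least as extreme as the last significant one are flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("ROUT needs n >= 3")
    if not 0 < q < 100:
        raise ValueError("Q must be a percentage in (0, 100)")
    n = x.size
    center = _robust_location(x)
    resid = x - center
    rsdr = _rsdr(resid, k_params=1)
    if rsdr == 0:
        return np.arange(n), np.empty(0, dtype=int)
    order = np.argsort(-np.abs(resid), kind="stable")
    m_max = max(int(np.floor(0.3 * n)), 1)
    t = np.abs(resid[order]) / rsdr
    p = 2 * sst.t.sf(t, df=n - 1)
    last_sig = 0
    for j in range(1, m_max + 1):
        alpha_j = (q / 100.0) * (n - j + 1) / n
        if p[j - 1] < alpha_j:
            last_sig = j
    flagged = np.sort(order[:last_sig])
    kept = np.setdiff1d(np.arange(n), flagged)
    return kept, flagged
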