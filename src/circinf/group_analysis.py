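"""Group-level statistics over a cohort table.

The analysis pipeline mirrors a standard individual-differences workflow:
Spearman rank correlations with Benjamini-Hochberg false-discovery-rate
correction within a declared test family, median or trajectory splits
with two-sample comparisons (Mann-Whitney, Welch), repeated-measures
Wilcoxon tests, ordinary least-squares regression with demographic
covariates, and Bland-Altman method agreement.  A Shapiro-Wilk gate
selects parametric versus nonparametric defaults; Cohen's d always uses
the pooled standard deviation, with the sign following the (group A -
group B) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf
import pingouin as pg


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference, sign = mean(a) - mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def correlate_fdr(
    table: pd.DataFrame,
    variables: Sequence[str],
    family: str = "default",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlations with BH-FDR within one family.

    All listed variable pairs (or every unordered pair of `variables`)
    form the correction family; pairs involving a constant variable are
    flagged undefined and excluded from the family size.  Requires >= 3
    complete cases per pair.

    Returns a frame with columns var1, var2, rho, p, q, n, family.
    """
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(variables)
                 for b in variables[i + 1:]]
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 complete cases for ({a}, {b})")
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"var1": a, "var2": b, "rho": np.nan, "p": np.nan,
                         "n": n, "defined": False})
            continue
        res = stats.spearmanr(sub[a], sub[b])
        rows.append({"var1": a, "var2": b, "rho": float(res.statistic),
                     "p": float(res.pvalue), "n": n, "defined": True})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["defined"].to_numpy()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["family"] = family
    return out


def is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality gate used to pick test defaults."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return bool(stats.shapiro(x).pvalue > alpha)


@dataclass(frozen=True)
class GroupComparison:
    """One two-group (or paired) test result."""

    outcome: str
    groups: tuple[str, str]
    sizes: tuple[int, int]
    test: str
    statistic: float
    p: float
    effect_size: float       # Cohen's d (pooled SD), sign = group[0] - group[1]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "groups": list(self.groups),
            "sizes": list(self.sizes), "test": self.test,
            "statistic": self.statistic, "p": self.p,
            "effect_size": self.effect_size,
        }


def median_split(
    table: pd.DataFrame, split_var: str, labels: tuple[str, str] = ("low", "high")
) -> pd.Series:
    """Median split with ties assigned to the low group."""
    x = table[split_var]
    med = x.median()
    return pd.Series(np.where(x <= med, labels[0], labels[1]), index=table.index)


def delta_sign_split(
    table: pd.DataFrame, delta_var: str, labels: tuple[str, str] = ("dec", "inc")
) -> pd.Series:
    """Trajectory split on the sign of a change score; zero changes excluded."""
    x = table[delta_var]
    out = pd.Series(pd.NA, index=table.index, dtype="object")
    out[x < 0] = labels[0]
    out[x > 0] = labels[1]
    return out


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    outcome: str = "",
    groups: tuple[str, str] = ("A", "B"),
    test: str = "auto",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Two-sample comparison with the configured or gate-selected test.

    `test` is one of auto, mann_whitney, welch_t; with auto, Welch's t is
    used when both groups pass the Shapiro-Wilk gate and Mann-Whitney
    otherwise.  One-sided ("oriented") alternatives are an explicit
    argument, never inferred from the data.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "auto":
        test = "welch_t" if (is_normal(a) and is_normal(b)) else "mann_whitney"
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    elif test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    name = test + ("" if alternative == "two-sided" else f"_{alternative}")
    return GroupComparison(
        outcome=outcome, groups=groups, sizes=(a.size, b.size), test=name,
        statistic=float(res.statistic), p=float(res.pvalue),
        effect_size=cohens_d(a, b),
    )


def split_and_compare(
    table: pd.DataFrame,
    split_var: str,
    outcome_vars: Sequence[str],
    split: str = "median",
    test: str = "auto",
    alternative: str = "two-sided",
) -> list[GroupComparison]:
    """Split the cohort on one variable and compare outcomes across groups.

    `split` is "median" (ties to the low group) or "delta_sign" (negative
    changes vs positive, zeros excluded).  The effect-size sign follows
    (first group - second group): low - high, or dec - inc.
    """
    if split == "median":
        labels = ("low", "high")
        groups = median_split(table, split_var, labels)
    elif split == "delta_sign":
        labels = ("dec", "inc")
        groups = delta_sign_split(table, split_var, labels)
    else:
        raise ValueError(f"unknown split {split!r}")
    out = []
    for var in outcome_vars:
        a = table.loc[groups == labels[0], var].to_numpy()
        b = table.loc[groups == labels[1], var].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group when splitting on {split_var}")
        out.append(
            compare_groups(a, b, outcome=var, groups=labels, test=test,
                           alternative=alternative)
        )
    return out


def paired_wilcoxon(x1: np.ndarray, x2: np.ndarray, outcome: str = "") -> GroupComparison:
    """Wilcoxon signed-rank test for repeated measures (x2 vs x1)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x2 - x1
    if np.all(diffs == 0):
        stat, p = 0.0, float("nan")
    else:
        stat, p = stats.wilcoxon(x2, x1)
    sd = diffs.std(ddof=1)
    d = float(diffs.mean() / sd) if sd > 0 else 0.0
    return GroupComparison(
        outcome=outcome, groups=("t2", "t1"), sizes=(x1.size, x2.size),
        test="wilcoxon_signed_rank", statistic=float(stat), p=float(p),
        effect_size=d,
    )


def welch_anova(table: pd.DataFrame, outcome: str, group: str) -> dict:
    """Welch's heteroscedastic one-way ANOVA with classical eta-squared."""
    res = pg.welch_anova(data=table, dv=outcome, between=group)
    groups = [g[outcome].to_numpy() for _, g in table.groupby(group)]
    grand = table[outcome].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = ((table[outcome] - grand) ** 2).sum()
    return {
        "test": "welch_anova",
        "F": float(res["F"].iloc[0]),
        "df1": float(res["ddof1"].iloc[0]),
        "df2": float(res["ddof2"].iloc[0]),
        "p": float(res["p_unc"].iloc[0]),
        "eta_squared": float(ss_between / ss_total) if ss_total > 0 else 0.0,
    }


def fit_covariate_regression(
    table: pd.DataFrame, outcome: str, predictors: Sequence[str]
) -> dict:
    """OLS regression of `outcome` on `predictors` (categoricals encoded).

    String/categorical predictors (e.g. country) enter as treatment-coded
    factors.  Raises on rank deficiency, naming the collinear columns.
    Returns the coefficient table plus adjusted R^2 and the overall F test.
    """
    terms = []
    for pvar in predictors:
        if table[pvar].dtype == object or str(table[pvar].dtype) == "category":
            terms.append(f"C({pvar})")
        else:
            terms.append(pvar)
    formula = f"{outcome} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the offending columns: those whose removal restores full rank
        names = model.exog_names
        bad = [
            names[j] for j in range(exog.shape[1])
            if np.linalg.matrix_rank(np.delete(exog, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    res = model.fit()
    coef = pd.DataFrame({
        "term": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    return {
        "coefficients": coef,
        "adj_r_squared": float(res.rsquared_adj),
        "f_statistic": float(res.fvalue),
        "f_p": float(res.f_pvalue),
        "n": int(res.nobs),
    }


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between two measurement methods on paired cases."""

    mean_difference: float
    loa_low: float
    loa_high: float
    sd_difference: float
    outside: np.ndarray      # boolean per case, True if outside the limits

    @property
    def n_outside(self) -> int:
        return int(self.outside.sum())


def bland_altman(x1: np.ndarray, x2: np.ndarray) -> BlandAltman:
    """Bland-Altman limits of agreement: mean(x1 - x2) +/- 1.96 SD."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape:
        raise ValueError("paired samples must have equal length")
    if x1.size < 3:
        raise ValueError("need at least 3 paired cases")
    diff = x1 - x2
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = (diff < lo) | (diff > hi)
    return BlandAltman(mean_difference=mean, loa_low=float(lo),
                       loa_high=float(hi), sd_difference=sd, outside=outside)
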