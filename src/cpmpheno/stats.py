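"""Reporting statistics for cohort comparisons.

* Pearson χ² on contingency tables, without continuity correction at any
  table size (the convention needed to reproduce printed 2×k statistics).
* One-way ANOVA adjusted for gender: additive linear model
  value ~ group + gender with a Type II sum of squares for the group factor,
  plus the ω² effect size
  ω² = (SS_group − df_group·MS_error) / (SS_total + MS_error)
  labeled small/medium/large at 0.01/0.06/0.14.
* Scheffé post hoc comparisons on gender-adjusted means using the full-model
  mean squared error.
* Fisher LSD (unadjusted pairwise t tests with the pooled one-way error).
* Spearman rank correlation with a Fieller–Hartley–Pearson 95% CI
  (Fisher z transform, SE = sqrt(1.06/(n−3))).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ContingencyTable",
    "EffectMagnitude",
    "AnovaResult",
    "PairwiseComparison",
    "PairwiseComparisons",
    "SpearmanResult",
    "pearson_chi2",
    "anova_gender_controlled",
    "omega_squared_magnitude",
    "scheffe_pairwise",
    "fisher_lsd_pairwise",
    "spearman_ci",
]


@dataclass
class ContingencyTable:
    """Integer cross-tabulation: outcome categories (rows) × groups (columns)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


class EffectMagnitude(str, Enum):
    NEGLIGIBLE = "NEGLIGIBLE"
    SMALL = "SMALL"
    MEDIUM = "MEDIUM"
    LARGE = "LARGE"


@dataclass
class AnovaResult:
    F_group: float
    df_group: int
    df_error: int
    p_value: float
    omega_sq: float
    magnitude: EffectMagnitude
    ms_error: float
    adjusted_means: dict[str, float]
    group_sizes: dict[str, int]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_value: float


@dataclass
class PairwiseComparisons:
    method: str  # "SCHEFFE" | "FISHER_LSD"
    comparisons: list[PairwiseComparison]

    def p(self, a: str, b: str) -> float:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c.p_value
        raise KeyError(f"no comparison for pair ({a}, {b})")


@dataclass
class SpearmanResult:
    rho: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def pearson_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson χ² statistic Σ(O−E)²/E with E = row·col/total, df=(r−1)(c−1),
    no continuity correction. Zero marginals are rejected by name."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2×2")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    for i in np.nonzero(row_sums == 0)[0]:
        raise ValueError(f"zero marginal for row {table.row_labels[i]!r}")
    for j in np.nonzero(col_sums == 0)[0]:
        raise ValueError(f"zero marginal for column {table.col_labels[j]!r}")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def _validate_groups(values, group_labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels).astype(str)
    if y.shape[0] != g.shape[0]:
        raise ValueError("values and group labels differ in length")
    groups = sorted(set(g))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    return y, g, groups


def anova_gender_controlled(values, group_labels, gender_labels) -> AnovaResult:
    """F test for the group factor in the additive model
    value ~ group + gender (Type II SS), with ω² for the group factor."""
    y, g, groups = _validate_groups(values, group_labels)
    sex = np.asarray(gender_labels).astype(str)
    if sex.shape[0] != y.shape[0]:
        raise ValueError("values and gender labels differ in length")
    if len(set(sex)) != 2:
        raise ValueError("gender must be binary")

    df = pd.DataFrame({"value": y, "group": g, "gender": sex})
    # perfect confounding makes the additive design singular
    model = smf.ols("value ~ C(group) + C(gender)", data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("group factor is confounded with gender; model is singular")
    fit = model.fit()
    table = anova_lm(fit, typ=2)

    ss_group = float(table.loc["C(group)", "sum_sq"])
    df_group = int(table.loc["C(group)", "df"])
    ss_error = float(table.loc["Residual", "sum_sq"])
    df_error = int(table.loc["Residual", "df"])
    ms_error = ss_error / df_error
    F = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    ss_total = float(((y - y.mean()) ** 2).sum())
    omega = (ss_group - df_group * ms_error) / (ss_total + ms_error)

    adjusted = _adjusted_means(fit, df, groups)
    sizes = {grp: int((g == grp).sum()) for grp in groups}
    return AnovaResult(
        F_group=F,
        df_group=df_group,
        df_error=df_error,
        p_value=p,
        omega_sq=float(omega),
        magnitude=omega_squared_magnitude(omega),
        ms_error=float(ms_error),
        adjusted_means=adjusted,
        group_sizes=sizes,
    )


def _adjusted_means(fit, df: pd.DataFrame, groups: list[str]) -> dict[str, float]:
    """Gender-adjusted group means: model predictions per group averaged over
    the cohort's observed gender distribution."""
    out = {}
    for grp in groups:
        counter = df.assign(group=grp)
        out[grp] = float(fit.predict(counter).mean())
    return out


def omega_squared_magnitude(omega: float) -> EffectMagnitude:
    if omega < 0.01:
        return EffectMagnitude.NEGLIGIBLE
    if omega < 0.06:
        return EffectMagnitude.SMALL
    if omega < 0.14:
        return EffectMagnitude.MEDIUM
    return EffectMagnitude.LARGE


def scheffe_pairwise(values, group_labels, gender_labels) -> PairwiseComparisons:
    """Scheffé post hoc comparisons after the gender-adjusted ANOVA.

    For each pair, S = Δ² / (MS_error (1/n_a + 1/n_b)) with Δ the
    gender-adjusted mean difference; p = 1 − F_cdf(S/(k−1); k−1, df_error).
    """
    res = anova_gender_controlled(values, group_labels, gender_labels)
    groups = sorted(res.adjusted_means)
    k = len(groups)
    comps = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = res.adjusted_means[a] - res.adjusted_means[b]
            denom = res.ms_error * (1.0 / res.group_sizes[a] + 1.0 / res.group_sizes[b])
            S = diff**2 / denom
            p = float(sps.f.sf(S / (k - 1), k - 1, res.df_error))
            comps.append(PairwiseComparison(a, b, float(diff), p))
    return PairwiseComparisons(method="SCHEFFE", comparisons=comps)


def fisher_lsd_pairwise(values, group_labels) -> PairwiseComparisons:
    """Fisher's least-significant-difference: unadjusted pairwise t tests
    using the pooled one-way MS_error (df = N − k)."""
    y, g, groups = _validate_groups(values, group_labels)
    sizes = {grp: int((g == grp).sum()) for grp in groups}
    if min(sizes.values()) < 2:
        singles = [grp for grp, n in sizes.items() if n < 2]
        raise ValueError(f"singleton group(s): {', '.join(singles)}")
    k = len(groups)
    n_total = y.shape[0]
    means = {grp: float(y[g == grp].mean()) for grp in groups}
    ss_error = sum(float(((y[g == grp] - means[grp]) ** 2).sum()) for grp in groups)
    df_error = n_total - k
    ms_error = ss_error / df_error
    comps = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = means[a] - means[b]
            se = np.sqrt(ms_error * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / se
                p = float(2 * sps.t.sf(abs(t), df_error))
            comps.append(PairwiseComparison(a, b, float(diff), p))
    return PairwiseComparisons(method="FISHER_LSD", comparisons=comps)


def spearman_ci(x, y, alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation (average ranks for ties) with a
    Fieller–Hartley–Pearson confidence interval: Fisher z transform of rho
    with SE = sqrt(1.06/(n−3)), back-transformed. Two-sided p from the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y differ in length")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt(1.06 / (n - 3))
    zcrit = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return SpearmanResult(rho=rho, ci95=(float(lo), float(hi)), p_value=float(p), n=n)
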