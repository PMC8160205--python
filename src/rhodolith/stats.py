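"""Regression, ANOVA, Newman-Keuls letters and assumption checks.

One-way ANOVA is computed directly from the sums of squares (fast enough to
run thousands of null simulations); the two-way crossed design is delegated
to statsmodels OLS/anova_lm behind the same result type. The Newman-Keuls
post hoc uses studentized-range critical values evaluated numerically from
scipy's distribution, so it works at arbitrary error degrees of freedom, and
emits a compact letter display via the standard insert-and-absorb algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import InsufficientReplicationError


# ---------------------------------------------------------------- regression

@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares fit with a pointwise 95% confidence band."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    slope_se: float
    n: int
    conf_band: pd.DataFrame     # columns x, fit, lower, upper

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        return "\n".join([
            "OLS regression",
            "--------------",
            f"slope:     {self.slope:.5g} (SE {self.slope_se:.3g})",
            f"intercept: {self.intercept:.5g}",
            f"R^2:       {self.r2:.4f}",
            f"p (slope): {self.p_value:.4g}   n = {self.n}",
        ])


def linear_regression(x, y, band_points: int = 50) -> RegressionResult:
    """OLS of y on x with slope test and 95% pointwise confidence band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise InsufficientReplicationError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), band_points)
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    band = pd.DataFrame({
        "x": grid, "fit": pred.predicted_mean,
        "lower": ci[:, 0], "upper": ci[:, 1],
    })
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        slope_se=float(fit.bse[1]),
        n=len(x),
        conf_band=band,
    )


# -------------------------------------------------------------------- ANOVA

@dataclass(frozen=True)
class AnovaTerm:
    name: str
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    terms: tuple[AnovaTerm, ...]
    design: str                  # "one_way" | "two_way"
    mse: float                   # residual mean square
    df_error: int

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"{self.design.replace('_', '-')} ANOVA",
                 f"{'term':<20}{'F':>10}{'df':>10}{'p':>12}"]
        for t in self.terms:
            lines.append(f"{t.name:<20}{t.F:>10.3f}{f'{t.df1},{t.df2}':>10}{t.p:>12.4g}")
        return "\n".join(lines)


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the between/within sum-of-squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientReplicationError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    ms_between = ss_between / df1
    mse = ss_within / df2
    F = ms_between / mse if mse > 0 else (0.0 if ss_between == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(
        terms=(AnovaTerm("group", float(F), df1, df2, p),),
        design="one_way", mse=float(mse), df_error=df2,
    )


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str) -> AnovaResult:
    """Fully crossed two-way fixed-effects ANOVA with interaction.

    Sums of squares are identical across types for balanced designs; an
    imbalance triggers a warning and type-II sums of squares.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise KeyError(col)
    cells = data.groupby([factor_a, factor_b]).size()
    n_a = data[factor_a].nunique()
    n_b = data[factor_b].nunique()
    if len(cells) < n_a * n_b:
        raise InsufficientReplicationError("missing cell in the crossed design")
    balanced = cells.nunique() == 1
    if not balanced:
        warnings.warn("unbalanced design: using type-II sums of squares")
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data
    ).fit()
    table = anova_lm(model, typ=1 if balanced else 2)
    df_error = int(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / df_error)
    names = {0: factor_a, 1: factor_b, 2: f"{factor_a}:{factor_b}"}
    terms = []
    row_idx = [i for i in table.index if i != "Residual"]
    for j, idx in enumerate(row_idx):
        terms.append(AnovaTerm(
            name=names[j], F=float(table.loc[idx, "F"]),
            df1=int(table.loc[idx, "df"]), df2=df_error,
            p=float(table.loc[idx, "PR(>F)"]),
        ))
    return AnovaResult(terms=tuple(terms), design="two_way", mse=mse, df_error=df_error)


# ----------------------------------------------------------- Newman-Keuls

@dataclass(frozen=True)
class PosthocLetters:
    """Compact letter display: groups sharing a letter are not separable."""

    group_labels: tuple[str, ...]
    alpha: float
    significant_pairs: frozenset[tuple[int, int]]

    def __iter__(self):
        return iter(self.group_labels)


def newman_keuls(groups, alpha: float = 0.05) -> PosthocLetters:
    """Stepwise Newman-Keuls studentized-range procedure on ordered means.

    Critical values come from the studentized-range distribution at the span
    of each stretch of ordered means; once a stretch is non-significant, all
    pairs inside it are declared non-significant (the step-down containment
    rule). Unequal group sizes use the harmonic-mean (Tukey-Kramer style)
    standard error. Returns a compact letter display over the groups in
    their input order.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientReplicationError("need >= 2 groups with >= 2 values each")
    an = one_way_anova(groups)
    mse, dfe = an.mse, an.df_error
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    order = np.argsort(means, kind="stable")     # ties broken by input order
    sig: set[tuple[int, int]] = set()

    if mse == 0:
        # degenerate: all within-group variance zero; any mean difference is real
        for a in range(k):
            for b in range(a + 1, k):
                if means[a] != means[b]:
                    sig.add((min(a, b), max(a, b)))
    else:
        def test(lo: int, hi: int):
            """Test the stretch of sorted means from position lo to hi."""
            if hi <= lo:
                return
            span = hi - lo + 1
            i, j = order[lo], order[hi]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                significant = means[j] != means[i]
            else:
                q_obs = (means[j] - means[i]) / se
                q_crit = sps.studentized_range.ppf(1.0 - alpha, span, dfe)
                significant = q_obs >= q_crit
            if significant:
                sig.add((min(i, j), max(i, j)))
                test(lo, hi - 1)
                test(lo + 1, hi)
            # non-significant stretch: containment rule, no sub-tests

        test(0, k - 1)

    labels = _compact_letters(k, sig)
    return PosthocLetters(group_labels=tuple(labels), alpha=alpha,
                          significant_pairs=frozenset(sig))


def _compact_letters(k: int, sig_pairs: set[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb compact letter display.

    Start from one letter covering all groups; for each significant pair,
    split every letter containing both; absorb letters that are subsets of
    another; assign letters in order of the sorted means.
    """
    columns: list[set[int]] = [set(range(k))]
    for (i, j) in sorted(sig_pairs):
        new_cols = []
        for col in columns:
            if i in col and j in col:
                a, b = col - {i}, col - {j}
                new_cols.extend([a, b])
            else:
                new_cols.append(col)
        # absorb duplicates/subsets
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if not any(col <= other for other in columns):
                columns.append(col)
    # letters in first-appearance order over the groups as given, matching
    # how rate tables print superscripts column by column
    columns.sort(key=lambda col: min(col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = ["" for _ in range(k)]
    for letter, col in zip(alphabet, columns):
        for g in col:
            labels[g] += letter
    return ["".join(sorted(s)) for s in labels]


# ------------------------------------------------------- assumption checks

@dataclass(frozen=True)
class AssumptionReport:
    """Advisory normality and homoscedasticity checks; never gates analysis."""

    shapiro_p: tuple[float, ...]
    levene_p: float
    degenerate: bool

    @property
    def normality_ok(self) -> bool:
        return all(p > 0.05 for p in self.shapiro_p if np.isfinite(p))

    @property
    def homoscedastic(self) -> bool:
        return not np.isfinite(self.levene_p) or self.levene_p > 0.05


def assumption_checks(groups) -> AssumptionReport:
    """Shapiro-Wilk per group and Levene across groups; constant data flagged."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        raise InsufficientReplicationError("assumption checks need n >= 3 per group")
    degenerate = any(np.ptp(g) == 0 for g in groups)
    shapiro_p = []
    for g in groups:
        if np.ptp(g) == 0:
            shapiro_p.append(float("nan"))
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    if degenerate and all(np.ptp(g) == 0 for g in groups):
        levene_p = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            levene_p = float(sps.levene(*groups).pvalue)
    return AssumptionReport(shapiro_p=tuple(shapiro_p), levene_p=levene_p,
                            degenerate=degenerate)
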