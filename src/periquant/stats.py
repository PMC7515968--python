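"""Group-level inference and reporting conventions.

Two-group comparison (Welch t by default, classical pooled Student t by
flag), two-way ANOVA with Tukey-HSD-corrected pairwise cell comparisons, and
the mean ± SD / significance-star formatting used throughout the reports.
The default inferential unit is the animal mean, wired from
:mod:`periquant.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "significance_stars",
    "format_mean_sd",
    "two_group_test",
    "two_way_anova_tukey",
]


def significance_stars(p: float) -> str:
    """'*' for p<0.05, '**' for p<0.01, '***' for p<0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def format_mean_sd(values: Sequence[float], decimals: int = 3, unit: str = "") -> str:
    """Report style ``mean ± SD`` at 3 decimals, e.g. ``30.221 ± 5.524%``."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return f"{m:.{decimals}f} ± {sd:.{decimals}f}{unit}"


@dataclass
class GroupComparison:
    """Result of one two-group test with report formatting attached."""

    label_a: str
    label_b: str
    values_a: list[float]
    values_b: list[float]
    statistic: float
    df: float
    p: float
    stars: str
    degenerate: bool = False

    def summary(self, unit: str = "") -> str:
        return (
            f"{self.label_a}: {format_mean_sd(self.values_a, unit=unit)} vs "
            f"{self.label_b}: {format_mean_sd(self.values_b, unit=unit)}; "
            f"t({self.df:.1f}) = {self.statistic:.3f}, P = {self.p:.4g} [{self.stars}]"
        )


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = True,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided two-sample t test on animal-level values.

    Welch–Satterthwaite df by default; ``welch=False`` gives the classical
    pooled-variance Student t.  The degenerate case (zero variance in both
    groups with equal means) is reported as t=0, p=1 and flagged.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if len(av) < 2 or len(bv) < 2:
        raise ValueError("each group needs at least 2 observations")
    degenerate = av.std(ddof=1) == 0 and bv.std(ddof=1) == 0
    if degenerate and np.isclose(av.mean(), bv.mean()):
        df = len(av) + len(bv) - 2
        return GroupComparison(
            label_a, label_b, av.tolist(), bv.tolist(),
            statistic=0.0, df=float(df), p=1.0, stars="ns", degenerate=True,
        )
    res = sps.ttest_ind(av, bv, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    return GroupComparison(
        label_a, label_b, av.tolist(), bv.tolist(),
        statistic=float(res.statistic), df=df, p=p,
        stars=significance_stars(p), degenerate=bool(degenerate),
    )


def two_way_anova_tukey(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    name_a: str = "treatment",
    name_b: str = "volume_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (type II) with Tukey-HSD pairwise cell comparisons.

    Returns ``(effects, pairwise)``: F and p per main effect and interaction,
    and Tukey-adjusted p for every pair of factor-level cells.  Requires at
    least 2 levels per factor and 2 observations per cell (empty cells are
    an error naming the cell).  The all-constant degenerate design (zero
    residual variance everywhere) is reported as F=0, p=1 for every effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {"value": np.asarray(list(values), dtype=float),
         "A": list(factor_a), "B": list(factor_b)}
    )
    la, lb = df["A"].unique(), df["B"].unique()
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for a in la:
        for b in lb:
            n = len(df[(df["A"] == a) & (df["B"] == b)])
            if n < 2:
                raise ValueError(
                    f"cell ({name_a}={a}, {name_b}={b}) has {n} observations (< 2)"
                )
    effect_index = [name_a, name_b, f"{name_a}:{name_b}"]
    if np.allclose(df["value"], df["value"].iloc[0]):
        effects = pd.DataFrame(
            {"F": [0.0] * 3, "p": [1.0] * 3}, index=effect_index
        )
        cells = (df["A"] + "/" + df["B"]).unique()
        pairs = [
            {"group1": g1, "group2": g2, "meandiff": 0.0, "p_adj": 1.0, "reject": False}
            for i, g1 in enumerate(cells) for g2 in cells[i + 1:]
        ]
        return effects, pd.DataFrame(pairs)
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    tbl = sm.stats.anova_lm(model, typ=2)
    effects = pd.DataFrame(
        {
            "F": [tbl.loc["C(A)", "F"], tbl.loc["C(B)", "F"], tbl.loc["C(A):C(B)", "F"]],
            "p": [
                tbl.loc["C(A)", "PR(>F)"],
                tbl.loc["C(B)", "PR(>F)"],
                tbl.loc["C(A):C(B)", "PR(>F)"],
            ],
        },
        index=effect_index,
    )
    cell = (df["A"] + "/" + df["B"]).to_numpy()
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), cell)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[c.replace("-", "_") for c in tk.summary().data[0]]
    ).rename(columns={"p_adj": "p_adj"})
    pairwise["p_adj"] = tk.pvalues
    return effects, pairwise
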