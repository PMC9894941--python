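"""Group-comparison layer: pooled-variance t-test and two-way ANOVA.

The study compares per-animal endpoints (pulse frequency, amplitude, mean
LH, percent diestrus, fold changes, ...) with an unpaired two-tailed
Student's t-test or a two-way ANOVA at alpha = 0.05, with no
multiple-testing correction. Both designs are reproduced here: the pooled
t from its closed form, the ANOVA via statsmodels OLS with Type II sums
of squares (immaterial on the balanced designs the simulator produces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "two_group_t", "two_way_anova"]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test on one endpoint.

    df is (df1,) for a t-test and (df_num, df_den) for an ANOVA F term.
    For a t-test with zero pooled variance the contract is: equal means
    give t = 0, p = 1; unequal means give t = +/-inf, p = 0 (flagged by
    the infinite statistic rather than an exception).
    """

    endpoint: str
    design: str
    term: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def two_group_t(
    values_a,
    values_b,
    alpha: float = ALPHA_DEFAULT,
    endpoint: str = "",
    term: str = "a_vs_b",
) -> ComparisonResult:
    """Unpaired two-tailed Student's t-test with pooled variance.

    t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b)), df = n_a+n_b-2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = float(diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(
        endpoint=endpoint,
        design="two_group_t",
        term=term,
        statistic=t,
        df=(float(df),),
        p_value=p,
        alpha=alpha,
    )


def two_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    factors: tuple[str, str] = ("group", "diet"),
    alpha: float = ALPHA_DEFAULT,
    endpoint: str = "",
) -> list[ComparisonResult]:
    """Two-way ANOVA with both main effects and the interaction.

    Expects a tidy table with one row per animal. Requires >= 2 levels per
    factor and >= 1 observation per cell. Type II sums of squares.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    df = table[[fa, fb, value_col]].rename(columns={value_col: "y"}).copy()
    if df["y"].isna().any():
        raise ValueError("missing endpoint values")
    for f in (fa, fb):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = df.groupby([fa, fb], observed=True).size()
    if len(cells) < df[fa].nunique() * df[fb].nunique():
        raise ValueError("empty factor cell")

    model = smf.ols(f"y ~ C({fa}) * C({fb})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    df_resid = float(aov.loc["Residual", "df"])
    # zero within-cell variance makes every F a 0/0 or x/0 ratio; resolve
    # terms by whether their sum of squares is numerically zero
    total_ss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    tol = 1e-12 * max(total_ss, 1.0)
    degenerate = float(aov.loc["Residual", "sum_sq"]) < tol
    term_names = {
        f"C({fa})": fa,
        f"C({fb})": fb,
        f"C({fa}):C({fb})": f"{fa}:{fb}",
    }
    results = []
    for row_name, term in term_names.items():
        f_stat = float(aov.loc[row_name, "F"])
        p = float(aov.loc[row_name, "PR(>F)"])
        if degenerate:
            if float(aov.loc[row_name, "sum_sq"]) < tol:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = float("inf"), 0.0
        elif np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
        elif np.isinf(f_stat) or np.isnan(p):
            p = 0.0
        results.append(
            ComparisonResult(
                endpoint=endpoint,
                design="two_way_anova",
                term=term,
                statistic=f_stat,
                df=(float(aov.loc[row_name, "df"]), df_resid),
                p_value=p,
                alpha=alpha,
            )
        )
    return results
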