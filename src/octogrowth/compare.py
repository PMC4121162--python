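"""Between-group growth-curve comparison and supporting statistics.

The analysis-of-residual-sum-of-squares (ARSS) F-test asks whether groups
(hatch seasons, sexes) share one growth curve: a pooled fit (one curve for
all data) is compared against separate per-group fits of the same model,

    F = [(RSS_pooled - RSS_separate) / df_num] / [RSS_separate / df_den],

with df_num = k(K-1) and df_den = N - kK for a k-parameter model and K
groups.  Both fits must minimise the same weighted objective for the
nesting (RSS_separate <= RSS_pooled) to hold, so the comparison uses fixed
weights derived from the observed data, never per-fit reweighting.

Also here: a profile-likelihood Box-Cox transform and a two-way
fixed-effects ANOVA (Type II sums of squares, robust to unbalanced data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import PARAM_NAMES, FitError, fit_model

__all__ = [
    "ComparisonResult",
    "AnovaTable",
    "arss_compare",
    "boxcox_transform",
    "normalize_response",
    "two_way_anova",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Result of the ARSS pooled-vs-separate curve comparison.

    ``df_den_alt``/``p_value_alt`` carry the alternative denominator
    convention df = N - k (pooled-residual df), logged alongside the
    primary k(K-1), N - kK convention.
    """

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_pooled: float
    rss_separate: float
    groups: tuple[str, ...]
    df_den_alt: int
    p_value_alt: float


def arss_compare(
    data_by_group: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    model: str = "gompertz",
    weighting: str = "data_sq",
) -> ComparisonResult:
    """ARSS F-test comparing one pooled curve against per-group curves.

    ``data_by_group`` maps a group label to its (ages, mantle weights).
    Weights are fixed per observation (``data_sq`` gives 1/m^2; ``none``
    is unweighted) and shared between the pooled and separate fits.
    """
    if len(data_by_group) < 2:
        raise ValueError("need at least 2 groups to compare")
    if weighting not in ("data_sq", "none"):
        raise ValueError("arss_compare requires a fixed weighting: 'data_sq' or 'none'")
    k = len(PARAM_NAMES[model])
    groups = tuple(sorted(data_by_group))
    ages_all = np.concatenate([np.asarray(data_by_group[g][0], float) for g in groups])
    mass_all = np.concatenate([np.asarray(data_by_group[g][1], float) for g in groups])
    N = len(ages_all)
    K = len(groups)

    try:
        pooled = fit_model(ages_all, mass_all, model=model, weighting=weighting)
    except (FitError, ValueError) as exc:
        raise FitError(f"pooled fit failed: {exc}") from exc
    rss_pooled = pooled.rss_weighted
    rss_sep = 0.0
    for g in groups:
        a, m = data_by_group[g]
        try:
            # warm-start each group at the pooled optimum for stability
            f = fit_model(
                np.asarray(a, float),
                np.asarray(m, float),
                model=model,
                weighting=weighting,
                theta0=pooled.params.theta,
            )
        except (FitError, ValueError) as exc:
            raise FitError(f"fit failed for group {g!r}: {exc}") from exc
        rss_sep += f.rss_weighted

    df_num = k * (K - 1)
    df_den = N - k * K
    if df_den <= 0:
        raise ValueError("not enough data for the separate-fits degrees of freedom")
    f_stat = max(rss_pooled - rss_sep, 0.0) / df_num / (rss_sep / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    df_den_alt = N - k
    f_alt = max(rss_pooled - rss_sep, 0.0) / df_num / (rss_sep / df_den_alt)
    p_alt = float(stats.f.sf(f_alt, df_num, df_den_alt))
    return ComparisonResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        rss_pooled=float(rss_pooled),
        rss_separate=float(rss_sep),
        groups=groups,
        df_den_alt=df_den_alt,
        p_value_alt=p_alt,
    )


def boxcox_transform(
    values: Sequence[float], grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
) -> tuple[np.ndarray, float]:
    """Box-Cox power transform with lambda chosen by profile likelihood.

    The profile log-likelihood is maximised on the grid [-2, 2] in steps of
    0.01; the transform is (y^lam - 1)/lam for lam != 0 and ln y at lam = 0.
    All values must be strictly positive.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("values must be a 1-D sequence with n >= 2")
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    ll = np.array([stats.boxcox_llf(l, y) for l in lams])
    lam = float(lams[int(np.argmax(ll))])
    lam = 0.0 if abs(lam) < step / 2 else lam
    if lam == 0.0:
        return np.log(y), 0.0
    return (np.power(y, lam) - 1.0) / lam, lam


def normalize_response(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, float | None, float]:
    """Box-Cox an ANOVA response only when a Shapiro-Wilk check fails.

    Returns (possibly transformed values, the lambda used or None when no
    transform was applied, the Shapiro-Wilk p-value of the raw data).
    """
    y = np.asarray(values, dtype=float)
    p_raw = float(stats.shapiro(y).pvalue)
    if p_raw >= alpha:
        return y, None, p_raw
    transformed, lam = boxcox_transform(y)
    return transformed, lam, p_raw


@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects ANOVA table (Type II sums of squares).

    ``table`` has one row per term (factors, interaction if estimable,
    residual) with columns sum_sq, df, F, PR(>F).  ``inestimable`` lists
    terms that could not be estimated (e.g. interaction with empty cells).
    """

    table: pd.DataFrame
    inestimable: tuple[str, ...] = ()

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def two_way_anova(
    response: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Two-way crossed fixed-effects ANOVA with Type II sums of squares.

    Factors with a single level are dropped (the design degrades to one-way
    or, with both single, raises). An interaction term that is inestimable
    because of empty cells is flagged, not silently dropped. A constant
    response yields zero sums of squares with F reported as 0 and p as 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(response, dtype=float)
    a = pd.Series([str(v) for v in factor_a], name=names[0])
    b = pd.Series([str(v) for v in factor_b], name=names[1])
    if not (len(y) == len(a) == len(b)):
        raise ValueError("response and factors must have equal length")
    df = pd.DataFrame({"y": y, names[0]: a.values, names[1]: b.values})

    terms = [n for n in names if df[n].nunique() > 1]
    if not terms:
        raise ValueError("both factors have a single level; nothing to test")
    inestimable: list[str] = []
    formula = "y ~ " + " + ".join(f"C({t})" for t in terms)
    if len(terms) == 2:
        cells = df.groupby([names[0], names[1]], observed=True).size()
        full_grid = df[names[0]].nunique() * df[names[1]].nunique()
        if len(cells) == full_grid:
            formula += f" + C({names[0]}):C({names[1]})"
        else:
            inestimable.append(f"{names[0]}:{names[1]}")
    n_params = sum(df[t].nunique() - 1 for t in terms) + 1
    if len(y) <= n_params:
        raise ValueError("not enough observations for the requested design")

    model = smf.ols(formula, data=df).fit()
    if np.ptp(y) == 0.0:  # constant response: guard the 0/0 F ratios
        tab = anova_lm(model, typ=2)
        tab["F"] = 0.0
        tab["PR(>F)"] = 1.0
        tab.loc["Residual", ["F", "PR(>F)"]] = np.nan
        return AnovaTable(table=_clean_index(tab, names), inestimable=tuple(inestimable))
    tab = anova_lm(model, typ=2)
    return AnovaTable(table=_clean_index(tab, names), inestimable=tuple(inestimable))


def _clean_index(tab: pd.DataFrame, names: tuple[str, str]) -> pd.DataFrame:
    def clean(ix: str) -> str:
        out = ix
        for n in names:
            out = out.replace(f"C({n})", n)
        return out

    tab = tab.copy()
    tab.index = [clean(str(i)) for i in tab.index]
    return tab
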