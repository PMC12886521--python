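"""Nested group comparisons and correlations on metric tables.

Arterioles (the observations) are nested within mice (the independent
units): a mouse contributing six vessels must not count three times as
much as one contributing two.  Comparisons therefore operate at the mouse
level — each mouse enters as the mean of its arterioles — which weighs
every animal equally and is exactly equivalent to the random-intercept
nested model in balanced designs.  Variance components (between-mouse and
within-mouse) are estimated from the classical nested-ANOVA expected mean
squares and reported alongside every test.

For two groups the result is a nested t-test; for more levels a one-way
ANOVA with Tukey-style pairwise follow-ups on the studentized-range
distribution at mouse-level degrees of freedom; for two crossed factors
(e.g. group x sex) a two-way ANOVA on mouse means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NestedTestResult",
    "CorrelationResult",
    "nested_compare",
    "pearson_corr",
    "summarize_by_mouse",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "amplitude_pct",
    "t_max_s",
    "t_amp50_s",
    "auc_pct_s",
    "basal_diameter_um",
)


@dataclass
class NestedTestResult:
    """Outcome of a nested group comparison on one metric."""

    metric: str
    factors: tuple[str, ...]
    effect: float  # group difference on the metric's scale (2 levels)
    se: float
    df: float  # mouse-level denominator degrees of freedom
    statistic: float  # t (2 levels) or omnibus F
    p_value: float
    var_between_mouse: float
    var_within_mouse: float
    pairwise: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def _variance_components(table: pd.DataFrame, metric: str, group_col: str):
    """Between-mouse and within-mouse variance via nested-ANOVA EMS.

    Uses the unbalanced-design coefficient n0 = (N - sum n_j^2 / N) /
    (J - g) for the expected mean squares; negative between-mouse
    estimates are truncated at zero.
    """
    y = table[metric].to_numpy(dtype=float)
    mice = table["mouse_id"].to_numpy()
    groups = table[group_col].to_numpy()
    mouse_ids, mouse_idx = np.unique(mice, return_inverse=True)
    n_j = np.bincount(mouse_idx)
    mouse_means = np.bincount(mouse_idx, weights=y) / n_j
    ss_within = float(((y - mouse_means[mouse_idx]) ** 2).sum())
    n_total = len(y)
    n_mice = len(mouse_ids)
    df_within = n_total - n_mice
    ms_within = ss_within / df_within if df_within > 0 else 0.0

    # mouse-within-group sum of squares, weighted by vessels per mouse
    mouse_group = pd.Series(groups, index=mice).groupby(level=0).first()
    grp_of_mouse = mouse_group.loc[mouse_ids].to_numpy()
    g_levels, g_idx = np.unique(grp_of_mouse, return_inverse=True)
    grp_tot = np.bincount(g_idx, weights=mouse_means * n_j)
    grp_n = np.bincount(g_idx, weights=n_j.astype(float))
    grp_means = grp_tot / grp_n
    ss_mouse = float((n_j * (mouse_means - grp_means[g_idx]) ** 2).sum())
    df_mouse = n_mice - len(g_levels)
    ms_mouse = ss_mouse / df_mouse if df_mouse > 0 else 0.0
    # expected-mean-square coefficient for mice nested in groups:
    # E[MS_mouse] = sigma_w^2 + n0 * sigma_b^2
    sum_sq_over_group = np.bincount(g_idx, weights=n_j.astype(float) ** 2) / grp_n
    n0 = (n_total - sum_sq_over_group.sum()) / df_mouse if df_mouse > 0 else 1.0
    var_between = max(0.0, (ms_mouse - ms_within) / n0)
    return var_between, ms_within


def nested_compare(
    table: pd.DataFrame,
    metric: str,
    factors: str | list[str] = "group",
) -> NestedTestResult:
    """Compare groups on one metric, respecting the mouse hierarchy.

    ``factors`` names one or two between-mouse columns of ``table``
    (e.g. ``"group"`` or ``["group", "sex"]``).  Every cell must contain
    at least two mice, otherwise no between-mouse variance is estimable
    and the comparison is rejected.
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table")
    for f in factors:
        if f not in table.columns:
            raise KeyError(f"factor {f!r} not in table")

    # one observation per mouse: the mean over its arterioles
    mouse_means = (
        table.groupby(["mouse_id", *factors], observed=True)[metric]
        .mean()
        .reset_index()
    )
    cell_counts = mouse_means.groupby(factors, observed=True)["mouse_id"].nunique()
    if (cell_counts < 2).any():
        bad = cell_counts[cell_counts < 2].index.tolist()
        raise ValueError(f"cells with a single mouse: {bad}; nested test undefined")

    var_between, var_within = _variance_components(table, metric, factors[0])

    if len(factors) == 2:
        return _two_way(mouse_means, metric, tuple(factors), var_between, var_within)

    factor = factors[0]
    levels = list(pd.unique(mouse_means[factor]))
    vals = [mouse_means.loc[mouse_means[factor] == g, metric].to_numpy() for g in levels]
    n = np.array([len(v) for v in vals])
    means = np.array([v.mean() for v in vals])
    j_total = int(n.sum())
    df_err = j_total - len(levels)
    ss_err = float(sum(((v - m) ** 2).sum() for v, m in zip(vals, means)))
    ms_err = ss_err / df_err

    if len(levels) == 2:
        # nested t-test: ordinary two-sample t on mouse means
        effect = float(means[1] - means[0])
        se = float(np.sqrt(ms_err * (1 / n[0] + 1 / n[1])))
        tstat = effect / se
        p = float(2 * sps.t.sf(abs(tstat), df_err))
        return NestedTestResult(
            metric, (factor,), effect, se, df_err, tstat, p, var_between, var_within
        )

    grand = float(np.average(means, weights=n))
    ss_grp = float((n * (means - grand) ** 2).sum())
    ms_grp = ss_grp / (len(levels) - 1)
    fstat = ms_grp / ms_err
    p = float(sps.f.sf(fstat, len(levels) - 1, df_err))
    pairwise = _tukey(levels, means, n, ms_err, df_err)
    return NestedTestResult(
        metric,
        (factor,),
        float(means.max() - means.min()),
        float(np.sqrt(ms_err * 2 / n.mean())),
        df_err,
        fstat,
        p,
        var_between,
        var_within,
        pairwise=pairwise,
    )


def _tukey(levels, means, n, ms_err, df_err) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons on the studentized range."""
    rows = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[j] - means[i])
            se = np.sqrt(ms_err / 2 * (1 / n[i] + 1 / n[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "difference": diff,
                    "q": float(q),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _two_way(mouse_means, metric, factors, var_between, var_within) -> NestedTestResult:
    """Two-way ANOVA (type II) on mouse means for crossed between-mouse factors."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = mouse_means.rename(columns={metric: "_y"})
    f1, f2 = factors
    model = ols(f"_y ~ C({f1}) * C({f2})", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    main = anova.loc[f"C({f1})"]
    return NestedTestResult(
        metric,
        factors,
        float("nan"),
        float("nan"),
        float(anova.loc["Residual", "df"]),
        float(main["F"]),
        float(main["PR(>F)"]),
        var_between,
        var_within,
        anova_table=anova,
    )


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson correlation with its best linear fit.

    Two-sided p-value from the t transform of r; slope and intercept from
    ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    lr = sps.linregress(x, y)
    return CorrelationResult(
        float(lr.rvalue), float(lr.pvalue), len(x), float(lr.slope), float(lr.intercept)
    )


def summarize_by_mouse(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mouse-level mean +/- SD of a metric, per timepoint when present.

    A mouse with a single arteriole has no within-mouse SD; it is reported
    as 0 with ``sd_defined = False``.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table")
    keys = ["mouse_id"]
    for extra in ("group", "timepoint"):
        if extra in table.columns:
            keys.append(extra)
    agg = (
        table.groupby(keys, observed=True)[metric]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_pas="count")
        .reset_index()
    )
    agg["sd_defined"] = agg["n_pas"] > 1
    agg["sd"] = agg["sd"].fillna(0.0)
    return agg
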