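"""Screening and inference chain for per-neuron OxD tables.

The chain mirrors common practice in quantitative redox imaging:

1. intactness screen — only neurons with an OxD between 5 % and 95 %
   of the sensor response range are considered intact and kept;
2. ROUT outlier screen at Q = 1 % (robust fit + FDR on residuals),
   applied per (region, genotype, age) column;
3. aggregation at the cell level and, slice-first, at the tissue-slice
   level (mean of per-slice means);
4. two-way ANOVA (genotype x age) per region with all-pairwise
   Holm-Šídák-adjusted comparisons, and Welch's t-test where two
   unpaired groups with unequal variances are compared.

Tables are plain pandas DataFrames with the ``NeuronRecord`` column
schema (see ``NEURON_COLUMNS``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "NEURON_COLUMNS",
    "WelchResult",
    "aggregate",
    "apply_rout",
    "filter_intact",
    "holm_sidak_adjust",
    "rout_outliers",
    "significance_marker",
    "two_way_anova_holm_sidak",
    "welch_t",
]

#: Canonical column schema of a per-neuron record table.
NEURON_COLUMNS = (
    "cell_id",
    "slice_id",
    "region",
    "genotype",
    "age_group",
    "ratio",
    "oxd",
    "mecp2_positive",
    "included",
    "exclusion_reason",
)

OXD_INTACT_RANGE = (0.05, 0.95)


def significance_marker(p: float, symbol: str = "*") -> str:
    """Two-level significance marker: one symbol for p<0.05, two for p<0.01."""
    if p < 0.01:
        return symbol * 2
    if p < 0.05:
        return symbol
    return ""


def filter_intact(
    cells: pd.DataFrame,
    lo: float = OXD_INTACT_RANGE[0],
    hi: float = OXD_INTACT_RANGE[1],
) -> pd.DataFrame:
    """Apply the intactness screen: keep 0.05 <= OxD <= 0.95 (closed).

    Returns a copy with ``included`` / ``exclusion_reason`` updated:
    out-of-range cells get reason ``"range"``; cells whose OxD is
    undefined (NaN) get ``"undefined_oxd"``.  Already-excluded rows keep
    their reason.  Idempotent.
    """
    out = cells.copy()
    if "included" not in out:
        out["included"] = True
    if "exclusion_reason" not in out:
        out["exclusion_reason"] = None
    oxd = out["oxd"].to_numpy(dtype=float)
    undefined = ~np.isfinite(oxd)
    out_of_range = ~undefined & ((oxd < lo) | (oxd > hi))
    newly = out["included"].to_numpy(dtype=bool) & (undefined | out_of_range)
    out.loc[newly & undefined, "exclusion_reason"] = "undefined_oxd"
    out.loc[newly & out_of_range, "exclusion_reason"] = "range"
    out.loc[newly, "included"] = False
    return out


def rout_outliers(
    values: Sequence[float], q: float = 0.01, max_outlier_fraction: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier detection reduced to the constant model.

    Robust fit: centre = median, robust scale = the 68.27th percentile of
    the absolute residuals with the small-sample correction n/(n-1)
    (the percentile that equals one SD for a Gaussian).  Each point gets
    a t-like statistic |residual|/scale and a two-sided tail probability
    from the t distribution with n-1 df; points are flagged by the
    Benjamini–Hochberg step-up rule at false-discovery rate ``q``,
    examining at most the most extreme ``max_outlier_fraction`` of the
    sample.

    Returns (kept_mask, flagged_mask) as boolean arrays over the input.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("ROUT requires at least 3 values")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    resid = x - np.median(x)
    abs_resid = np.abs(resid)
    scale = np.percentile(abs_resid, 68.27) * n / (n - 1)
    flagged = np.zeros(n, dtype=bool)
    if scale <= 0:
        # >68 % of points identical: anything that deviates at all is
        # infinitely many robust SDs away
        nonzero = abs_resid > 0
        if nonzero.any():
            flagged[nonzero] = True
        return ~flagged, flagged
    t_stat = abs_resid / scale
    pvals = 2.0 * sps.t.sf(t_stat, df=n - 1)
    order = np.argsort(pvals)  # most extreme residual first
    max_k = max(1, int(np.floor(max_outlier_fraction * n)))
    k_star = 0
    for rank, idx in enumerate(order[:max_k], start=1):
        if pvals[idx] <= q * rank / n:
            k_star = rank
    flagged[order[:k_star]] = True
    return ~flagged, flagged


def apply_rout(
    cells: pd.DataFrame,
    q: float = 0.01,
    by: Sequence[str] = ("region", "genotype", "age_group"),
    response: str = "oxd",
) -> pd.DataFrame:
    """Run the ROUT screen per group column on the included cells.

    Flagged cells are excluded with reason ``"rout_outlier"``.  Groups
    with fewer than 3 included cells are left untouched.
    """
    out = cells.copy()
    for _, idx in out[out["included"]].groupby(list(by)).groups.items():
        vals = out.loc[idx, response].to_numpy(dtype=float)
        if len(vals) < 3:
            continue
        _, flagged = rout_outliers(vals, q=q)
        bad = np.asarray(idx)[flagged]
        out.loc[bad, "included"] = False
        out.loc[bad, "exclusion_reason"] = "rout_outlier"
    return out


def aggregate(
    cells: pd.DataFrame,
    level: str = "cell",
    by: Sequence[str] = ("region", "genotype", "age_group"),
    response: str = "oxd",
) -> pd.DataFrame:
    """Group summaries (mean, SD, n) at the cell or tissue-slice level.

    ``level="cell"`` averages neurons directly.  ``level="slice"``
    first averages the neurons within each slice, then summarises the
    per-slice means — so n counts slices, and under unequal slice sizes
    the slice-level mean deliberately differs from the cell-level mean.
    Only included cells enter; an SD over a single observation is NaN.
    """
    df = cells[cells["included"]].copy()
    if level == "slice":
        df = (
            df.groupby([*by, "slice_id"], observed=True)[response]
            .mean()
            .reset_index()
        )
    elif level != "cell":
        raise ValueError("level must be 'cell' or 'slice'")
    grouped = df.groupby(list(by), observed=True)[response]
    summary = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    summary["level"] = level
    return summary


def holm_sidak_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm–Šídák step-down adjustment of a family of p-values.

    Sorted ascending, p_(i) becomes 1 - (1 - p_(i))^(k - i + 1); the
    adjusted values are then made monotone non-decreasing in the
    step-down order and returned in the original input order.
    """
    p = np.asarray(pvals, dtype=float)
    k = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (k - np.arange(k))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(k)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""

    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    @property
    def marker(self) -> str:
        return significance_marker(self.p, "#")


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test between two independent groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if len(g) < 2:
            raise ValueError(f"group {name} needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return WelchResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
    )


@dataclass
class ComparisonResult:
    """Two-way ANOVA with all-pairwise Holm-Šídák comparisons.

    ``anova`` holds the F table (factor A, factor B, interaction);
    ``pairwise`` one row per contrast with raw and adjusted p and the
    significance marker (asterisks for age contrasts, crosshatches for
    genotype contrasts, both symbols for crossed contrasts);
    ``group_summary`` mean ± SD with n per design cell.  ``anova`` is
    None when a design cell is empty.
    """

    factors: tuple[str, str]
    response: str
    anova: pd.DataFrame | None
    pairwise: pd.DataFrame
    group_summary: pd.DataFrame
    test_name: str = "two-way ANOVA + Holm-Sidak all-pairwise"


def _contrast_symbol(level_a: tuple, level_b: tuple, factors: tuple[str, str]) -> str:
    """Asterisk for a pure factor-B (age) contrast, crosshatch for pure
    factor-A (genotype), both when the contrast crosses both factors."""
    symbol = ""
    if level_a[0] != level_b[0]:
        symbol += "#"
    if level_a[1] != level_b[1]:
        symbol += "*"
    return symbol or "*"


def two_way_anova_holm_sidak(
    cells: pd.DataFrame,
    factors: tuple[str, str] = ("genotype", "age_group"),
    response: str = "oxd",
) -> ComparisonResult:
    """Two-way ANOVA with marginal (Type III) sums of squares and
    all-pairwise Holm-Šídák comparisons among the design cells.

    The unbalanced 2x2 design is fit with sum-to-zero factor coding;
    pairwise contrasts among the group means use t statistics on the
    pooled ANOVA residual variance and are adjusted as one Holm-Šídák
    family.  Rows where ``included`` is False are dropped when the
    column is present.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = cells.copy()
    if "included" in df:
        df = df[df["included"]]
    fa, fb = factors
    df = df.dropna(subset=[fa, fb, response])

    groups = df.groupby([fa, fb], observed=True)[response]
    summary = groups.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()

    levels_a = sorted(df[fa].unique())
    levels_b = sorted(df[fb].unique())
    complete = len(summary) == len(levels_a) * len(levels_b) and (summary["n"] >= 2).all()

    anova_table = None
    if complete and len(levels_a) >= 2 and len(levels_b) >= 2:
        data = df.rename(columns={fa: "_A", fb: "_B", response: "_y"})
        fit = smf.ols("_y ~ C(_A, Sum) * C(_B, Sum)", data=data).fit()
        anova_table = sm.stats.anova_lm(fit, typ=3)
        mse = float(fit.mse_resid)
        dof = float(fit.df_resid)
    else:
        # fall back to the pooled within-group variance of the non-empty cells
        pooled_num = 0.0
        dof = 0.0
        for _, g in groups:
            if len(g) > 1:
                pooled_num += (len(g) - 1) * g.var(ddof=1)
                dof += len(g) - 1
        mse = pooled_num / dof if dof > 0 else float("nan")

    cells_list = [tuple(r) for r in summary[[fa, fb]].itertuples(index=False)]
    rows = []
    for i in range(len(cells_list)):
        for j in range(i + 1, len(cells_list)):
            ga, gb = cells_list[i], cells_list[j]
            ra = summary.iloc[i]
            rb = summary.iloc[j]
            se = np.sqrt(mse * (1.0 / ra["n"] + 1.0 / rb["n"]))
            if se > 0 and dof > 0:
                t = (ra["mean"] - rb["mean"]) / se
                p = float(2.0 * sps.t.sf(abs(t), df=dof))
            else:
                t, p = float("nan"), 1.0
            rows.append(
                {
                    "contrast": f"{ga[0]}/{ga[1]} vs {gb[0]}/{gb[1]}",
                    "level_a": ga,
                    "level_b": gb,
                    "t": float(t) if np.isfinite(t) else t,
                    "p_raw": p,
                    "symbol": _contrast_symbol(ga, gb, factors),
                }
            )
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_adj"] = holm_sidak_adjust(pairwise["p_raw"].to_numpy())
        pairwise["marker"] = [
            significance_marker(p, "#" if sym == "#" else "*")
            for p, sym in zip(pairwise["p_adj"], pairwise["symbol"])
        ]
    return ComparisonResult(
        factors=factors,
        response=response,
        anova=anova_table,
        pairwise=pairwise,
        group_summary=summary,
    )
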