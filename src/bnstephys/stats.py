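"""ANOVA and Tukey HSD machinery for the feature comparisons.

Two-way fixed-effects ANOVA (neuron type × stimulus step, both categorical,
no repeated factors) with Type-III sums of squares under sum-to-zero
contrasts, which is appropriate for the unbalanced cell sizes that arise
when neuron types have different n.  One-way ANOVA and Tukey's HSD
(studentized-range based, Tukey-Kramer for unequal n) for the post-hoc
pairwise comparisons.  Summaries are mean ± SEM per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    cell_counts: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    diff: float            # mean_a - mean_b
    p_adj: float
    ci_low: float
    ci_high: float


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]

    def p_adj(self, a, b) -> float:
        for pr in self.pairs:
            if {pr.group_a, pr.group_b} == {str(a), str(b)}:
                return pr.p_adj
        raise KeyError((a, b))


class DesignError(ValueError):
    """Raised for degenerate ANOVA designs (empty cells, n=1 cells)."""


def _check_cells(df: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    la = sorted(df[a].unique())
    lb = sorted(df[b].unique())
    if len(la) < 2 or len(lb) < 2:
        raise DesignError("each factor needs at least 2 levels")
    counts = df.groupby([a, b], observed=True).size().unstack(fill_value=0)
    counts = counts.reindex(index=la, columns=lb, fill_value=0)
    empty = [(i, j) for i in la for j in lb if counts.loc[i, j] == 0]
    if empty:
        raise DesignError(f"empty design cell(s): {empty}")
    if (counts == 1).any().any():
        ones = [(i, j) for i in la for j in lb if counts.loc[i, j] == 1]
        raise DesignError(f"cell(s) with n = 1 cannot support ANOVA: {ones}")
    return counts


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, Type-III SS.

    Sum-to-zero contrasts make the Type-III tests invariant to the reference
    level, matching the convention of mainstream GUI statistics packages for
    unbalanced two-factor designs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "fa": [str(x) for x in factor_a],
        "fb": [str(x) for x in factor_b],
    })
    if df["value"].isna().any():
        df = df.dropna(subset=["value"])
    counts = _check_cells(df, "fa", "fb")

    model = smf.ols("value ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    df_den = float(tab.loc["Residual", "df"])

    key_map = {
        names[0]: "C(fa, Sum)",
        names[1]: "C(fb, Sum)",
        "interaction": "C(fa, Sum):C(fb, Sum)",
    }
    effects = {}
    for name, row_key in key_map.items():
        row = tab.loc[row_key]
        effects[name] = EffectResult(
            F=float(row["F"]), df_num=float(row["df"]),
            df_den=df_den, p=float(row["PR(>F)"]),
        )
    return AnovaResult(effects=effects, cell_counts=counts)


def one_way_anova(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over named groups."""
    from scipy import stats as sps

    arrs = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrs) < 2:
        raise DesignError("need at least 2 groups")
    if any(a.size < 2 for a in arrs.values()):
        raise DesignError("every group needs n >= 2")
    k = len(arrs)
    n = sum(a.size for a in arrs.values())
    F, p = sps.f_oneway(*arrs.values())
    res = EffectResult(F=float(F), df_num=float(k - 1),
                       df_den=float(n - k), p=float(p))
    counts = pd.DataFrame({g: [a.size] for g, a in arrs.items()}, index=["n"])
    return AnovaResult(effects={"group": res}, cell_counts=counts)


def tukey_hsd(groups: dict[str, Sequence[float]],
              confidence: float = 0.95) -> TukeyResult:
    """Tukey's HSD over named groups (Tukey-Kramer for unequal n).

    Adjusted p-values come from the studentized range distribution with the
    pooled within-group error, so they are exact rather than interpolated.
    """
    from scipy import stats as sps

    names = [str(k) for k in groups]
    arrs = [np.asarray(groups[k], dtype=float) for k in groups]
    if len(arrs) < 2:
        raise DesignError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise DesignError("every group needs n >= 2")
    res = sps.tukey_hsd(*arrs)
    ci = res.confidence_interval(confidence_level=confidence)
    means = [float(a.mean()) for a in arrs]
    pairs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            pairs.append(TukeyPair(
                group_a=names[i], group_b=names[j],
                diff=means[i] - means[j],
                p_adj=float(res.pvalue[i, j]),
                ci_low=float(ci.low[i, j]),
                ci_high=float(ci.high[i, j]),
            ))
    return TukeyResult(pairs=pairs)


def summarize(values_by_group: dict[str, Sequence[float]]) -> pd.DataFrame:
    """mean, SEM and n per group (SEM NaN-flagged for single values)."""
    rows = []
    for g, v in values_by_group.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        n = arr.size
        mean = float(arr.mean()) if n else np.nan
        sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"group": str(g), "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows).set_index("group")
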