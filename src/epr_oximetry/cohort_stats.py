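"""Study-level statistics on per-tumour pO2, volumes and ordinal scores.

The group comparisons mirror the figure-caption conventions of small
xenograft studies: one-way fixed-effects ANOVA with post-hoc Tukey HSD
on pO2 (and on 0-3 ordinal immunohistochemistry scores, which reuse the
same operation), a per-timepoint two-group volume comparison (Welch by
default), and Pearson correlation between tumour volume and pO2 with the
exact t-transform p-value.

Per-tumour observations are treated as independent; animal-level
clustering is acknowledged but deliberately unmodelled (see the methods
note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import ValidationError

__all__ = [
    "GroupStats",
    "PearsonResult",
    "GrowthComparison",
    "anova_tukey",
    "pearson_correlation",
    "growth_comparison",
    "growth_significance_sweep",
]


@dataclass
class GroupStats:
    """One-way ANOVA + Tukey HSD results for one contrast family."""

    f_statistic: float
    anova_p: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    tukey_p: dict[tuple[str, str], float]
    significant_pairs: list[tuple[str, str]]
    alpha: float

    def summary(self) -> str:
        lines = [
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.4g}, p = {self.anova_p:.4g}",
            "group means (sd, n):",
        ]
        for g in sorted(self.group_means):
            lines.append(
                f"  {g}: {self.group_means[g]:.4g} "
                f"({self.group_sds[g]:.4g}, n={self.group_ns[g]})"
            )
        lines.append(f"Tukey HSD adjusted p (alpha = {self.alpha:g}):")
        for pair in sorted(self.tukey_p):
            star = " *" if pair in self.significant_pairs else ""
            lines.append(f"  {pair[0]} vs {pair[1]}: {self.tukey_p[pair]:.4g}{star}")
        return "\n".join(lines)


def anova_tukey(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> GroupStats:
    """One-way ANOVA (F, p) with Tukey HSD adjusted pairwise p-values.

    Tukey adjustment uses the studentized-range distribution; pairs with
    adjusted p below ``alpha`` are flagged. Degenerate all-equal data
    yields F = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: values[groups == g] for g in labels}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group '{g}' has n = {arr.size} < 2")

    grand = values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    dfb = len(labels) - 1
    dfw = values.size - len(labels)
    if ssb == 0.0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(sp_stats.f.sf(f_stat, dfb, dfw))

    tukey_p: dict[tuple[str, str], float] = {}
    if ssw == 0.0:
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                same = arrays[gi].mean() == arrays[gj].mean()
                tukey_p[(gi, gj)] = 1.0 if same else 0.0
    else:
        res = sp_stats.tukey_hsd(*[arrays[g] for g in labels])
        for i, gi in enumerate(labels):
            for j, gj in enumerate(labels):
                if i < j:
                    tukey_p[(gi, gj)] = float(res.pvalue[i, j])

    significant = [pair for pair, pv in tukey_p.items() if pv < alpha]
    return GroupStats(
        f_statistic=float(f_stat),
        anova_p=float(p),
        df_between=dfb,
        df_within=dfw,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        group_sds={g: float(a.std(ddof=1)) for g, a in arrays.items()},
        group_ns={g: int(a.size) for g, a in arrays.items()},
        tukey_p=tukey_p,
        significant_pairs=significant,
        alpha=alpha,
    )


@dataclass
class PearsonResult:
    r: float
    p: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson r with the exact two-sided t-transform p-value.

    ``t = r * sqrt((n-2)/(1-r^2))`` against Student's t on n-2 df;
    ``|r| = 1`` gives p = 0, ``r = 0`` gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation test")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("correlation undefined: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sp_stats.t.sf(abs(t), n - 2))
    return PearsonResult(r=r, p=p, n=n)


@dataclass
class GrowthComparison:
    day: int
    means: dict[str, float]
    ns: dict[str, int]
    p: float
    significant: bool
    test: str


def growth_comparison(
    table: pd.DataFrame,
    day: int,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GrowthComparison:
    """Two-group tumour-volume comparison at one measurement day.

    Welch's two-sample t-test by default (``equal_var=True`` selects the
    pooled-variance variant). The table needs columns ``group``, ``day``
    and ``volume_mm3`` with exactly two groups present on that day.
    """
    for col in ("group", "day", "volume_mm3"):
        if col not in table.columns:
            raise ValidationError(f"cohort table missing column '{col}'")
    sub = table[table["day"] == day]
    if sub.empty:
        available = sorted(table["day"].unique().tolist())
        raise ValidationError(f"no volumes recorded on day {day}; "
                              f"available days: {available}")
    labels = sorted(sub["group"].unique().tolist())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups on day {day}, got {labels}")
    a = sub.loc[sub["group"] == labels[0], "volume_mm3"].to_numpy(float)
    b = sub.loc[sub["group"] == labels[1], "volume_mm3"].to_numpy(float)
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(sp_stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return GrowthComparison(
        day=int(day),
        means={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        ns={labels[0]: int(a.size), labels[1]: int(b.size)},
        p=p,
        significant=bool(p < alpha),
        test="pooled t" if equal_var else "Welch t",
    )


def growth_significance_sweep(
    table: pd.DataFrame, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Per-day significance pattern over every measurement day (tidy frame)."""
    rows = []
    for day in sorted(table["day"].unique().tolist()):
        gc = growth_comparison(table, int(day), alpha, equal_var)
        labels = sorted(gc.means)
        rows.append(
            {
                "day": gc.day,
                f"mean_{labels[0]}": gc.means[labels[0]],
                f"mean_{labels[1]}": gc.means[labels[1]],
                "p": gc.p,
                "significant": gc.significant,
            }
        )
    return pd.DataFrame(rows)
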