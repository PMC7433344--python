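"""Group statistics: unpaired Student t tests and mixed-design two-way ANOVA.

The battery mirrors standard behavioral-genetics reporting: genotype
contrasts use the two-tailed pooled-variance (Student) t test with
df = n1 + n2 - 2, accompanied by the variance-ratio F (larger/smaller sample
variance) as an equality-of-variances descriptor; startle amplitude tables
(animals x stimulus intensity) use a split-plot ("repetitive") two-way ANOVA
with a between-subjects genotype factor and a within-subjects intensity
factor, followed by Bonferroni-corrected per-intensity comparisons.

The variance ratio is +inf when exactly one group has zero variance (a group
that never shows a behavior has identically-zero measurements, and the ratio
degenerates accordingly) and 1 when both do.

Post hoc comparisons use per-intensity two-sample pooled t tests with alpha
divided by the number of intensities (adjusted p = raw p x levels, capped at
1) rather than the ANOVA residual mean square; the choice is localized in
:func:`bonferroni_posthoc` and swappable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TTestResult",
    "PosthocComparison",
    "MixedAnovaResult",
    "p_from_t",
    "p_from_f",
    "student_t_test",
    "mixed_anova",
    "mixed_anova_sums_of_squares",
    "format_p",
]


@dataclass(frozen=True)
class GroupSample:
    """A labelled per-animal measurement vector."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / math.sqrt(self.n))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    f_ratio: float
    f_df: tuple[int, int]


@dataclass(frozen=True)
class PosthocComparison:
    level: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class MixedAnovaResult:
    F_interaction: float
    df1: int
    df2: int
    p_interaction: float
    F_between: float
    p_between: float
    F_within: float
    p_within: float
    posthoc: tuple[PosthocComparison, ...]


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p for a t statistic: I_{df/(df+t^2)}(df/2, 1/2).

    Symmetric in the sign of t; accurate to better than 1e-6 (evaluated via
    the t survival function, i.e. the regularized incomplete beta).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def p_from_f(F: float, df1: int, df2: int) -> float:
    """Upper-tail p for an F statistic."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return float(sps.f.sf(F, df1, df2))


def _variance_ratio(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[int, int]]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        hi, lo, dfs = va, vb, (len(a) - 1, len(b) - 1)
    else:
        hi, lo, dfs = vb, va, (len(b) - 1, len(a) - 1)
    if lo == 0.0:
        return (1.0, dfs) if hi == 0.0 else (math.inf, dfs)
    return float(hi / lo), dfs


def student_t_test(a: GroupSample, b: GroupSample) -> TTestResult:
    """Two-tailed unpaired pooled-variance (Student) t test, df = n1 + n2 - 2.

    Degenerate cases are defined rather than NaN: with zero pooled variance,
    equal means give t = 0 (p = 1) and unequal means t = +/-inf (p = 0).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.n} and {b.n})")
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.values.var(ddof=1)
                  + (b.n - 1) * b.values.var(ddof=1)) / df
    se = math.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    diff = a.mean - b.mean
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = 1.0 if t == 0.0 else (0.0 if math.isinf(t) else p_from_t(t, df))
    f_ratio, f_df = _variance_ratio(a.values, b.values)
    return TTestResult(t=float(t), df=df, p=p, f_ratio=f_ratio, f_df=f_df)


def _check_table(table: pd.DataFrame, genotype: pd.Series) -> None:
    if table.isna().any().any():
        animal = table.index[table.isna().any(axis=1)][0]
        level = table.columns[table.isna().any(axis=0)][0]
        raise ValueError(
            f"incomplete table: animal {animal!r} is missing intensity {level!r}")
    groups = genotype.unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 genotype groups, got {list(groups)}")
    counts = genotype.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index[0]
        raise ValueError(f"group {small!r} has fewer than 2 animals")


def mixed_anova_sums_of_squares(table: pd.DataFrame,
                                genotype: pd.Series) -> dict[str, float]:
    """Split-plot sums of squares for an animals x levels table.

    Decomposes SS_total into genotype, between-subject error, level (within),
    genotype x level interaction, and within-subject error.  The design is
    balanced within (every animal contributes every level), which makes the
    weighted decomposition exact even with unequal group sizes.
    """
    y = table.to_numpy(dtype=float)
    n_subj, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    groups = list(pd.unique(genotype))
    ss = {"total": float(((y - grand) ** 2).sum())}
    ss["between_subjects"] = float(k * ((subj_means - grand) ** 2).sum())
    ss["genotype"] = float(sum(
        k * (genotype == g).sum() * (subj_means[(genotype == g).to_numpy()].mean() - grand) ** 2
        for g in groups))
    ss["error_between"] = ss["between_subjects"] - ss["genotype"]
    ss["level"] = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_inter = 0.0
    ss_err_within = 0.0
    for g in groups:
        sel = (genotype == g).to_numpy()
        yg = y[sel]
        gmean = yg.mean()
        cell = yg.mean(axis=0)
        ss_inter += sel.sum() * ((cell - gmean - level_means + grand) ** 2).sum()
        ss_err_within += ((yg - cell[None, :] - subj_means[sel, None] + gmean) ** 2).sum()
    ss["interaction"] = float(ss_inter)
    ss["error_within"] = float(ss_err_within)
    return ss


def bonferroni_posthoc(table: pd.DataFrame, genotype: pd.Series) -> tuple[PosthocComparison, ...]:
    """Per-level pooled two-sample t tests, Bonferroni-adjusted (x levels)."""
    groups = list(pd.unique(genotype))
    k = table.shape[1]
    out = []
    for level in table.columns:
        a = GroupSample(str(groups[0]), table.loc[(genotype == groups[0]).to_numpy(), level])
        b = GroupSample(str(groups[1]), table.loc[(genotype == groups[1]).to_numpy(), level])
        r = student_t_test(a, b)
        out.append(PosthocComparison(level=float(level), t=r.t, df=r.df,
                                     p_raw=r.p, p_adjusted=min(1.0, r.p * k)))
    return tuple(out)


def mixed_anova(table: pd.DataFrame, genotype: pd.Series) -> MixedAnovaResult:
    """Split-plot two-way ANOVA: between-subjects genotype x within-subjects level.

    ``table`` is an animals x levels DataFrame (one row per animal, one column
    per stimulus intensity); ``genotype`` labels the rows (exactly two groups,
    each with >= 2 animals).  The interaction F has df
    ((G-1)(k-1), (N-G)(k-1)) — (3, 3(N-2)) for the 2-genotype, 4-intensity
    design.  Returns between-group, within-subject and interaction effects
    plus Bonferroni post hoc per-level comparisons.
    """
    genotype = pd.Series(genotype, index=table.index) if not isinstance(genotype, pd.Series) \
        else genotype.reindex(table.index)
    _check_table(table, genotype)
    n_subj, k = table.shape
    n_groups = genotype.nunique()
    ss = mixed_anova_sums_of_squares(table, genotype)

    df_geno = n_groups - 1
    df_err_between = n_subj - n_groups
    df_level = k - 1
    df_inter = (n_groups - 1) * (k - 1)
    df_err_within = (n_subj - n_groups) * (k - 1)

    ms_err_between = ss["error_between"] / df_err_between
    ms_err_within = ss["error_within"] / df_err_within

    # sums of squares at round-off level (relative to SS_total) count as zero;
    # 0/0 arises for exactly additive noiseless tables and is defined as F = 0
    tiny = 1e-12 * max(ss["total"], 1.0)

    def _f(ss_effect: float, df_effect: int, ms_err: float) -> float:
        if ms_err <= tiny:
            return 0.0 if ss_effect <= tiny else math.inf
        return (ss_effect / df_effect) / ms_err

    F_between = _f(ss["genotype"], df_geno, ms_err_between)
    F_within = _f(ss["level"], df_level, ms_err_within)
    F_inter = _f(ss["interaction"], df_inter, ms_err_within)
    return MixedAnovaResult(
        F_interaction=float(F_inter),
        df1=df_inter,
        df2=df_err_within,
        p_interaction=p_from_f(F_inter, df_inter, df_err_within),
        F_between=float(F_between),
        p_between=p_from_f(F_between, df_geno, df_err_between),
        F_within=float(F_within),
        p_within=p_from_f(F_within, df_level, df_err_within),
        posthoc=bonferroni_posthoc(table, genotype),
    )


def format_p(p: float, decimals: int = 4) -> str:
    """Report-style p: 4 decimal places, '< 0.0001' below the printable floor."""
    floor = 10.0 ** -decimals
    if p < floor:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"
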