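"""The statistical battery applied to pipeline outputs.

One-way repeated-measures ANOVA (subject blocking) tests whether pennation
differs across joint positions; one-way ANOVA with Bonferroni-adjusted
pairwise post hoc tests compares per-muscle parameters within a group; a
Welch two-sample t-test compares groups. Following the study's decision
rule, when the within-group ANOVA over muscles finds no significant
difference, the three muscles are combined (per-subject mean) before the
group comparison.

The repeated-measures ANOVA is computed from its sums of squares directly
so every intermediate quantity is auditable; the tests cross-check it
against an independent implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sstats

from .errors import ValidationError


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_error: int
    p_value: float
    test: str


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    statistic: float
    df: float
    p_value: float
    test: str


def one_way_rm_anova(table) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Decomposes total variation into condition, subject, and residual sums
    of squares; F = MS_condition / MS_residual with (k-1, (n-1)(k-1))
    degrees of freedom.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValidationError("table has missing cells")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        # identical residuals: no within-subject variation beyond condition
        F = 0.0 if ss_cond <= 1e-300 else np.inf
    else:
        F = (ss_cond / df_cond) / ms_err
    p = 1.0 if F == 0.0 else float(sstats.f.sf(F, df_cond, df_err))
    return AnovaResult(float(F), df_cond, df_err, p, "one-way RM ANOVA")


def one_way_anova(groups) -> AnovaResult:
    """Ordinary one-way ANOVA across independent groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    F, p = sstats.f_oneway(*gs)
    df_b = len(gs) - 1
    df_e = sum(g.size for g in gs) - len(gs)
    if np.isnan(F):  # zero variance everywhere
        F, p = 0.0, 1.0
    return AnovaResult(float(F), df_b, df_e, float(p), "one-way ANOVA")


def two_sample_ttest(a, b, equal_var: bool = False) -> GroupComparison:
    """Two-sample t-test, Welch's (unequal variance) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 values per group")
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            df = float(a.size + b.size - 2)
        else:
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # both samples constant and equal
        stat, p = 0.0, 1.0
    return GroupComparison(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        stat, float(df), p, "Welch t-test" if not equal_var else "Student t-test",
    )


def anova_bonferroni(groups: dict[str, np.ndarray], equal_var: bool = False):
    """One-way ANOVA plus Bonferroni-adjusted pairwise post hoc t-tests.

    Adjusted p is the raw pairwise p multiplied by the number of
    comparisons k(k-1)/2, capped at 1.
    """
    names = list(groups)
    anova = one_way_anova([groups[n] for n in names])
    pairs = list(combinations(names, 2))
    m = len(pairs)
    posthoc = {}
    for na, nb in pairs:
        cmp_ = two_sample_ttest(groups[na], groups[nb], equal_var=equal_var)
        posthoc[(na, nb)] = {
            "raw_p": cmp_.p_value,
            "adjusted_p": min(1.0, cmp_.p_value * m),
            "statistic": cmp_.statistic,
        }
    return anova, posthoc


@dataclass(frozen=True)
class ExtensorGroupTest:
    """Result of the combine-then-test rule for the group stress comparison."""

    within_group_anova: dict[str, AnovaResult]
    combined: bool
    per_muscle_tests: dict[str, GroupComparison] | None
    combined_test: GroupComparison | None
    log: tuple[str, ...]


def compare_extensor_stress(
    control: dict[str, np.ndarray],
    stroke: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> ExtensorGroupTest:
    """Apply the study's decision rule to per-muscle stress estimates.

    Within each group, a one-way ANOVA asks whether the three heads differ.
    If neither group shows a significant difference, the per-subject mean
    across muscles is compared between groups with one t-test; otherwise
    each muscle is compared separately.
    """
    muscles = list(control)
    if list(stroke) != muscles:
        raise ValidationError("control and stroke tables must list the same muscles")
    log = []
    within = {}
    for label, table in (("control", control), ("stroke", stroke)):
        res = one_way_anova([table[m] for m in muscles])
        within[label] = res
        log.append(
            f"{label}: one-way ANOVA across muscles F({res.df_between},{res.df_error})"
            f"={res.F:.3f}, p={res.p_value:.4f}"
        )
    combine = all(res.p_value >= alpha for res in within.values())
    if combine:
        log.append("no significant muscle effect in either group: combining muscles "
                   "(per-subject mean) before the group t-test")
        a = np.mean([control[m] for m in muscles], axis=0)
        b = np.mean([stroke[m] for m in muscles], axis=0)
        test = two_sample_ttest(a, b)
        log.append(f"combined Welch t-test: t={test.statistic:.3f}, "
                   f"df={test.df:.1f}, p={test.p_value:.4f}")
        return ExtensorGroupTest(within, True, None, test, tuple(log))
    log.append("significant muscle effect: comparing groups per muscle")
    per = {m: two_sample_ttest(control[m], stroke[m]) for m in muscles}
    return ExtensorGroupTest(within, False, per, None, tuple(log))
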