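"""Replicate comparison statistics with significance star codes.

Clonal replicates of each strain × condition are summarized as mean ± SD;
groups are compared by one-way ANOVA, pairwise by Tukey's multiple
comparison test (Tukey–Kramer for unbalanced designs), or — for exactly two
groups — by the unpaired (pooled-variance) Student's t test. Significance is
coded the conventional way: * P<0.05, ** P<0.01, *** P<0.001, with strict
inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TukeyComparison",
    "GroupComparison",
    "summarize_replicates",
    "one_way_anova",
    "tukey_hsd",
    "two_sample_t",
    "star_code",
    "compare_groups",
]


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1 denominator) of replicate values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("at least two replicates are required for mean and SD")
    return float(v.mean()), float(v.std(ddof=1))


def _check_groups(groups: Sequence[Sequence[float]], k_min: int) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < k_min:
        raise ValueError(f"at least {k_min} groups are required")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p value.

    Degenerate inputs are resolved explicitly: with zero within-group
    variance, equal group means give F = 0 (p = 1) and unequal means give
    F = inf (p = 0).
    """
    arrays = _check_groups(groups, 2)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if ssw == 0.0:
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b)
    q: float  # studentized-range statistic
    p_adj: float


def tukey_hsd(
    groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
) -> list[TukeyComparison]:
    """All pairwise Tukey (HSD / Tukey–Kramer) comparisons.

    For each pair the mean difference, the studentized-range statistic
    q = |mi − mj| / sqrt(MSW/2 · (1/ni + 1/nj)), and the adjusted p value
    from the studentized-range distribution with k groups and N−k error
    degrees of freedom are returned. Balanced designs reduce to classic HSD;
    unbalanced ones use the Tukey–Kramer standard error.
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        arrays = _check_groups(list(groups.values()), 3)
    else:
        arrays = _check_groups(groups, 3)
        labels = [str(i) for i in range(len(arrays))]
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df = n_total - k
    msw = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays) / df
    out: list[TukeyComparison] = []
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = arrays[a], arrays[b]
            diff = float(ga.mean() - gb.mean())
            if msw == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df))
            out.append(TukeyComparison(labels[a], labels[b], diff, float(q), p))
    return out


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired Student's t test (pooled variance), two-sided.

    Degenerate zero-pooled-variance inputs give t = 0, p = 1 for equal means
    and a signed infinite t with p = 0 otherwise.
    """
    ga, gb = _check_groups([a, b], 2)
    ssw = float(np.sum((ga - ga.mean()) ** 2) + np.sum((gb - gb.mean()) ** 2))
    if ssw == 0.0:
        d = ga.mean() - gb.mean()
        if d == 0.0:
            return 0.0, 1.0
        return float(np.sign(d)) * float("inf"), 0.0
    t, p = stats.ttest_ind(ga, gb, equal_var=True)
    return float(t), float(p)


def star_code(p: float) -> str:
    """Significance code: *** P<0.001, ** P<0.01, * P<0.05, else "" (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """Per-group summaries and the comparison appropriate to the group count.

    ANOVA is always computed; Tukey pairwise comparisons are defined for
    three or more groups, the unpaired t test for exactly two. ``stars``
    maps each pairwise comparison (or the single t-test pair) to its
    significance code based on the adjusted p value.
    """

    labels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    anova_f: float = float("nan")
    anova_p: float = float("nan")
    tukey: list[TukeyComparison] = field(default_factory=list)
    ttest: tuple[float, float] | None = None
    stars: dict[tuple[str, str], str] = field(default_factory=dict)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Summarize and compare labeled replicate groups in one shot."""
    labels = list(groups.keys())
    arrays = _check_groups(list(groups.values()), 2)
    means, sds = {}, {}
    for lab, g in zip(labels, arrays):
        means[lab], sds[lab] = summarize_replicates(g)
    out = GroupComparison(labels=labels, means=means, sds=sds)
    out.anova_f, out.anova_p = one_way_anova(arrays)
    if len(arrays) == 2:
        out.ttest = two_sample_t(arrays[0], arrays[1])
        out.stars[(labels[0], labels[1])] = star_code(out.ttest[1])
    else:
        out.tukey = tukey_hsd(dict(zip(labels, arrays)))
        for c in out.tukey:
            out.stars[(c.group_a, c.group_b)] = star_code(c.p_adj)
    return out
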