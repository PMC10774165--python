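"""Group-comparison decision procedure for replicate growth/uptake data.

Two groups: Shapiro-Wilk normality screen on each group, then a two-tailed
Student t-test (equal variance) if both pass, otherwise a Mann-Whitney U
test (exact for small samples without ties).  More than two groups: one-way
ANOVA with Tukey HSD post hoc, summarised as a compact letter display where
two groups share a letter iff they are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TwoGroupReport", "compare_two_groups", "anova_tukey"]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TwoGroupReport:
    normality_p: tuple[float, float]
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p: float
    stars: str


def compare_two_groups(a, b, alpha: float = 0.05) -> TwoGroupReport:
    """Normality-gated two-group comparison.

    Each group needs n >= 3.  Degenerate input (zero variance in both
    groups, equal means) reports p = 1 with a zero t statistic rather than
    erroring, since "no evidence of a difference" is the right answer.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 measurements")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TwoGroupReport((1.0, 1.0), "t", 0.0, 1.0, "ns")
        # identical-within, different-between: t is infinite, p -> 0
        return TwoGroupReport((1.0, 1.0), "t", float("inf"), 0.0, "***")
    pa = 1.0 if a.std() == 0 else float(stats.shapiro(a).pvalue)
    pb = 1.0 if b.std() == 0 else float(stats.shapiro(b).pvalue)
    if pa >= alpha and pb >= alpha:
        res = stats.ttest_ind(a, b, equal_var=True)
        return TwoGroupReport((pa, pb), "t", float(res.statistic), float(res.pvalue), _stars(res.pvalue))
    combined = np.concatenate([a, b])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TwoGroupReport(
        (pa, pb), "mann_whitney", float(res.statistic), float(res.pvalue), _stars(res.pvalue)
    )


def anova_tukey(groups: dict[str, list[float]], alpha: float = 0.05) -> dict[str, str]:
    """One-way ANOVA + Tukey HSD, reported as a compact letter display.

    Two groups share a letter iff Tukey HSD finds them not significantly
    different at ``alpha``.  Letters are assigned by the insert-and-absorb
    algorithm over the non-significant pairs.
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey needs >= 3 groups (use compare_two_groups)")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} needs >= 3 measurements")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if all(a.std() == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        return {n: "a" for n in names}
    stats.f_oneway(*arrays)  # validates shapes; Tukey drives the letters
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    res = np.asarray(tk.reject, dtype=bool)
    # statsmodels orders pairs as combinations of sorted unique groups
    uniq = list(tk.groupsunique)
    combos = [(str(uniq[i]), str(uniq[j])) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    significant = {frozenset(c) for c, rej in zip(combos, res) if rej}
    return _letter_display(names, significant)


def _letter_display(names: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds the pairs that must NOT share a letter; every
    non-significant pair must share at least one.
    """
    letter_sets: list[set[str]] = [set(names)]
    for pair in sorted(significant, key=sorted):
        g1, g2 = sorted(pair)
        for ls in list(letter_sets):
            if g1 in ls and g2 in ls:
                letter_sets.remove(ls)
                s1, s2 = ls - {g2}, ls - {g1}
                for s in (s1, s2):
                    if not any(s <= other for other in letter_sets):
                        letter_sets.append(s)
    # absorb: drop sets contained in others (already handled), then order
    letter_sets.sort(key=lambda s: min(names.index(n) for n in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, ls in zip(alphabet, letter_sets):
        for n in names:
            if n in ls:
                out[n] += letter
    return out
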