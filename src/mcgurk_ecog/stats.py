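"""Hypothesis tests applied to pipeline outputs.

Two-sided tests throughout; exact small-sample distributions are used
where the sample permits and the usual normal approximations (with tie
correction) otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    comparison: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[TestResult]:
    """One-way ANOVA across groups plus all pairwise Tukey-Kramer
    comparisons (unequal group sizes handled by the Kramer adjustment).

    For behavioral use, each group is the per-trial correctness (0/1) of
    one category.  The first returned result is the omnibus ANOVA; the
    rest are one per group pair with Tukey-adjusted p-values.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    f_stat, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    results = [
        TestResult(
            name="anova",
            statistic=float(f_stat),
            p_value=float(p),
            n=n_total,
            comparison=" vs ".join(names),
        )
    ]
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    import itertools

    pair_names = [
        (tukey.groupsunique[i], tukey.groupsunique[j])
        for i, j in itertools.combinations(range(len(tukey.groupsunique)), 2)
    ]
    for (g1, g2), stat, padj in zip(
        pair_names, np.asarray(tukey.meandiffs), np.asarray(tukey.pvalues)
    ):
        results.append(
            TestResult(
                name="tukey_kramer",
                statistic=float(stat),
                p_value=float(min(max(padj, 0.0), 1.0)),
                n=n_total,
                comparison=f"{g1} vs {g2}",
            )
        )
    return results


def mannwhitney_diffspec(
    same_video_diffs: np.ndarray, same_audio_diffs: np.ndarray
) -> TestResult:
    """Two-sided Mann-Whitney U comparing the two samples of
    difference-spectrogram statistics (same-video vs same-audio matched
    comparisons)."""
    a = np.asarray(same_video_diffs, dtype=float)
    b = np.asarray(same_audio_diffs, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=a.size + b.size,
        comparison="same-video vs same-audio difference statistics",
    )


def wilcoxon_vs_chance(accuracies: np.ndarray, chance: float = 0.5) -> TestResult:
    """One-sample two-sided Wilcoxon signed-rank against the chance
    median.  Values exactly at chance are dropped (signed-rank
    convention); if all values equal chance the test is degenerate and
    reported as p = 1."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 5:
        raise ValueError("need at least 5 accuracy values")
    diffs = acc - chance
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult(
            name="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n=acc.size,
            comparison=f"accuracies vs chance {chance}",
        )
    res = sps.wilcoxon(nonzero, alternative="two-sided")
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=acc.size,
        comparison=f"accuracies vs chance {chance}",
    )
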