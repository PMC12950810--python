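"""Group statistics: median (Q1, Q3) summaries and the Kruskal-Wallis
test with Dunn's post-hoc pairwise comparisons (Bonferroni-adjusted).

The measured biophysical parameters are not normally distributed, so
groups are summarized by median and interquartile range and compared
with rank-based tests, mirroring the experimental analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "DunnResult", "KruskalDunnResult",
           "summarize_group", "kruskal_dunn", "significance_flag"]


@dataclass(frozen=True)
class GroupSummary:
    median: float
    q1: float
    q3: float
    n: int


@dataclass(frozen=True)
class DunnResult:
    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: tuple  # of DunnResult


def summarize_group(values) -> GroupSummary:
    """Median with quartiles by linear interpolation (type 7)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return GroupSummary(float(med), float(q1), float(q3), int(x.size))


def significance_flag(p: float) -> str:
    """Footnote-style flag: '' (ns), '*', '**', '***'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def kruskal_dunn(groups: dict[str, "np.ndarray"]) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise z-tests with
    Bonferroni adjustment over all k(k-1)/2 pairs.

    Returns H with tie correction, the omnibus p-value (chi-square
    approximation), and per-pair adjusted p-values.  Degenerate all-tied
    input yields H = 0, p = 1 and no significant pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")

    pooled = np.concatenate(samples)
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)

    ranks = sps.rankdata(pooled)
    sizes = [s.size for s in samples]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(samples))]

    # tie correction for the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = []
    m = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_un = 1.0 if se == 0 else 2.0 * sps.norm.sf(abs(z))
            pairs.append(DunnResult(labels[i], labels[j], float(z),
                                    float(p_un), float(min(1.0, p_un * m))))
    return KruskalDunnResult(float(h), float(p), tuple(pairs))
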