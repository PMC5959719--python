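"""Nonparametric group comparisons used throughout the analysis.

Two-group comparisons of cumulative distributions use the two-sample
Kolmogorov–Smirnov test; three or more groups are compared with
Kruskal–Wallis followed by Dunn's rank-based pairwise post-test with
Bonferroni family correction (the adjustment method is this package's
choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "ks_two_sample", "kruskal_dunn", "dunn_posthoc"]


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> GroupComparison:
    """Two-sample Kolmogorov–Smirnov test on cumulative distributions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    res = stats.ks_2samp(a, b)
    return GroupComparison("kolmogorov-smirnov", float(res.statistic), float(res.pvalue), (a.size, b.size))


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    labels = labels or [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": float(z),
                    "p_raw": float(p_raw),
                    "p_adjusted": float(min(p_raw * m, 1.0)),
                }
            )
    return pd.DataFrame(rows)


def kruskal_dunn(groups: list[np.ndarray], labels: list[str] | None = None) -> GroupComparison:
    """Kruskal–Wallis H test with Dunn's Bonferroni-adjusted post-hoc table."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis with Dunn post-test needs at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    h, p = stats.kruskal(*groups)
    posthoc = dunn_posthoc(groups, labels)
    return GroupComparison(
        "kruskal-wallis+dunn", float(h), float(p), tuple(g.size for g in groups), posthoc
    )
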