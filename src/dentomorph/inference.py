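"""Permutation and classical tests for shapes, sizes, and trait counts.

The mean-shape comparison uses a permutation test of the distance between
group mean tangent vectors with group sizes held fixed; the p-value follows
the ``(1 + exceedances) / (1 + permutations)`` convention, so it can never
be exactly zero. Size comparisons use the Mann-Whitney U test (normal
approximation with midranks, tie-corrected variance and 0.5 continuity
correction) and the Kruskal-Wallis test; trait prevalences use the Pearson
Chi-square test of independence without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PermutationTestResult",
    "permutation_mean_shape_test",
    "mann_whitney_u",
    "kruskal_wallis",
    "ContingencyTable",
    "chi_square_independence",
]


@dataclass
class PermutationTestResult:
    observed_statistic: float
    n_permutations: int
    p_value: float
    seed: int | None
    labels: tuple[str, str]
    null_distribution: np.ndarray | None = None


def permutation_mean_shape_test(
    tangent_coords: np.ndarray,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    keep_null: bool = False,
) -> PermutationTestResult:
    """Permutation test of the distance between two group mean shapes.

    The statistic is the Euclidean distance between the group mean tangent
    vectors (the Procrustes distance between group mean shapes, to first
    order). The null is built by relabeling specimens with the two group
    sizes fixed; ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``.
    """
    x = np.asarray(tangent_coords, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    mask = labels == uniq[0]
    n_a = int(mask.sum())
    n_b = len(labels) - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 specimens")

    def statistic(m):
        return float(np.linalg.norm(x[m].mean(axis=0) - x[~m].mean(axis=0)))

    observed = statistic(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(labels))
    for i in range(n_perm):
        perm = rng.permutation(idx)
        m = np.zeros(len(labels), dtype=bool)
        m[perm[:n_a]] = True
        null[i] = statistic(m)
    exceed = int(np.sum(null >= observed - 1e-15))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(
        observed, n_perm, p, seed, (str(uniq[0]), str(uniq[1])),
        null if keep_null else None,
    )


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U test, normal approximation (midranks, tie correction).

    Returns ``(U, Z, p)`` with U the statistic of the first sample, Z the
    absolute standardized statistic with 0.5 continuity correction, and a
    two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u1, 0.0, 1.0  # all observations identical
    z = (abs(u1 - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return u1, float(z), float(min(p, 1.0))


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected).

    Returns ``(H, df, p)`` with the p-value from the chi-square upper tail.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    if len(np.unique(np.concatenate(groups))) == 1:
        raise ValueError("all observations identical; H is undefined")
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


@dataclass
class ContingencyTable:
    """Group-by-class count table for trait prevalence testing."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if len(self.row_labels) != self.counts.shape[0]:
            raise ValueError("row label count mismatch")
        if len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("column label count mismatch")


def chi_square_independence(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson Chi-square test of independence, no continuity correction.

    Returns ``(chi2, df, p)``; expected counts come from the table margins.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("a row or column margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)
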