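"""Palm-vs-dicot group contrasts for per-tree metrics.

Two complementary tests suited to very small groups (here 2 palms vs 5
dicots): a one-sample t-test of the dicot values against the palm group
mean, and a label-permutation test on the difference in group means.  When
the number of distinct label arrangements is at most the requested
iteration count, the permutation null is enumerated exhaustively (e.g.
C(7,2) = 21 arrangements), giving an exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "GroupContrast",
    "group_means",
    "one_sample_t",
    "permutation_test",
    "group_contrast",
]


@dataclass(frozen=True)
class GroupContrast:
    """Full contrast report for one metric."""

    metric: str
    palm_mean: float
    palm_sd: float
    dicot_mean: float
    dicot_sd: float
    t_statistic: float
    t_p_value: float
    perm_p_value: float
    n_permutations: int
    seed: int | None


def group_means(values, groups):
    """Arithmetic mean ± sample sd (ddof=1) per group.

    Returns ``((palm_mean, palm_sd), (dicot_mean, dicot_sd))``; sd is NaN for
    a single-member group.  Raises if either group is empty.
    """
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    out = []
    for name in ("palm", "dicot"):
        sub = vals[grp == name]
        if sub.size == 0:
            raise ValueError(f"empty group {name!r}")
        sd = float(sub.std(ddof=1)) if sub.size > 1 else float("nan")
        out.append((float(sub.mean()), sd))
    return tuple(out)


def one_sample_t(dicot_values, palm_mean: float):
    """Two-sided one-sample t of the dicot values against the palm mean."""
    vals = np.asarray(dicot_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need ≥2 dicot values")
    if vals.std(ddof=1) == 0:
        raise ValueError("zero variance; t-test undefined")
    res = stats.ttest_1samp(vals, popmean=palm_mean)
    return float(res.statistic), float(res.pvalue)


def permutation_test(
    palm_values,
    dicot_values,
    n_perm: int = 5000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p for the difference in group means.

    Group labels are permuted uniformly; p is the proportion of arrangements
    whose absolute mean difference is at least the observed one, with the
    observed arrangement included (so p > 0).  All ``comb(n, n_palm)``
    distinct arrangements are enumerated when that count is ≤ ``n_perm``;
    otherwise ``n_perm`` Monte-Carlo permutations are drawn with ``seed``.
    """
    palm = np.asarray(palm_values, dtype=float)
    dicot = np.asarray(dicot_values, dtype=float)
    if palm.size == 0 or dicot.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([palm, dicot])
    n, n_palm = pooled.size, palm.size
    observed = abs(palm.mean() - dicot.mean())
    total = pooled.sum()

    def absdiff(palm_sum: float) -> float:
        return abs(palm_sum / n_palm - (total - palm_sum) / (n - n_palm))

    eps = 1e-12  # tolerate FP noise at |diff| == observed
    if comb(n, n_palm) <= n_perm:
        hits = sum(
            absdiff(sum(pooled[list(idx)])) >= observed - eps
            for idx in combinations(range(n), n_palm)
        )
        return hits / comb(n, n_palm)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if absdiff(pooled[perm[:n_palm]].sum()) >= observed - eps:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def group_contrast(
    metric: str,
    values,
    groups,
    n_perm: int = 5000,
    seed: int | None = None,
) -> GroupContrast:
    """Run both tests for one metric and bundle the results."""
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    (palm_mean, palm_sd), (dicot_mean, dicot_sd) = group_means(vals, grp)
    t, p_t = one_sample_t(vals[grp == "dicot"], palm_mean)
    p_perm = permutation_test(
        vals[grp == "palm"], vals[grp == "dicot"], n_perm=n_perm, seed=seed
    )
    return GroupContrast(
        metric=metric,
        palm_mean=palm_mean,
        palm_sd=palm_sd,
        dicot_mean=dicot_mean,
        dicot_sd=dicot_sd,
        t_statistic=t,
        t_p_value=p_t,
        perm_p_value=p_perm,
        n_permutations=n_perm,
        seed=seed,
    )
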