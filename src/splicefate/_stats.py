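"""Shared statistical primitives (Wilcoxon rank-sum with an exact small-sample path)."""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats

from .exceptions import InvalidArgumentError

__all__ = ["wilcoxon_rank_sum"]

# Full enumeration of group assignments is used for the exact path with ties;
# cap the number of distinct assignments so the test stays fast.
_MAX_ENUM = 200_000


def wilcoxon_rank_sum(x, y, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when both groups have <= ``exact_max`` observations: the exact
    Mann-Whitney null distribution when there are no ties, full enumeration
    of group assignments when there are ties and the enumeration is small.
    Otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all observations identical
        return 1.0

    small = x.size <= exact_max and y.size <= exact_max
    has_ties = np.unique(pooled).size < pooled.size
    if small and not has_ties:
        return float(stats.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue)
    if small and comb(x.size + y.size, x.size) <= _MAX_ENUM:
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.mannwhitneyu(a, b, method="asymptotic",
                                            use_continuity=False).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return float(min(1.0, res.pvalue))
    return float(
        stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True,
                           alternative="two-sided").pvalue
    )
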