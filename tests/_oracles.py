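"""Independent reference implementations used to check the package.

Everything here is deliberately naive — memoized pairwise recursion,
explicit matrix inversion, full enumeration — and shares no code with the
implementation under test.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


def kinship_oracle(parents: dict[str, tuple[str | None, str | None]]):
    """Pairwise kinship by the textbook recursion on a parent map.

    parents maps id -> (father, mother), founders to (None, None).
    Returns a function k(i, j).
    """

    @lru_cache(maxsize=None)
    def k(i: str, j: str) -> float:
        if i == j:
            f, m = parents[i]
            if f is None:
                return 0.5
            return 0.5 * (1.0 + k(f, m))
        # recurse on the individual with the later-defined parents; order the
        # pair so recursion always descends (ids are topologically sortable
        # by insertion order of the dict)
        order = list(parents)
        if order.index(i) < order.index(j):
            i, j = j, i
        f, m = parents[i]
        if f is None:
            return 0.0
        return 0.5 * (k(f, j) + k(m, j))

    return k


def ld_from_counts(n_ab: int, n_aB: int, n_Ab: int, n_AB: int) -> tuple[float, float]:
    """r^2 and D' straight from a 2-locus haplotype count table.

    Arguments are counts of haplotypes ab, aB, Ab, AB (capital = derived
    allele present).
    """
    n = n_ab + n_aB + n_Ab + n_AB
    p_a = (n_Ab + n_AB) / n  # derived at locus A
    p_b = (n_aB + n_AB) / n
    p_ab = n_AB / n
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d == 0 else abs(d) / d_max
    return r2, dprime


def wilcoxon_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Doubles the smaller one-sided tail probability of the Mann-Whitney U
    statistic (midrank ties handled by enumerating assignments of the
    observed values), capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(first_idx: tuple[int, ...]) -> float:
        a = pooled[list(first_idx)]
        b = np.delete(pooled, list(first_idx))
        # U = #(a > b) + 0.5 #(a == b)
        gt = np.sum(a[:, None] > b[None, :])
        eq = np.sum(a[:, None] == b[None, :])
        return float(gt + 0.5 * eq)

    u_obs = u_stat(tuple(range(n)))
    us = [u_stat(idx) for idx in combinations(range(n + m), n)]
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def gls_oracle(y, x, v) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least squares by explicit inversion: beta and cov(beta)/sigma2."""
    v_inv = np.linalg.inv(v)
    xtvx_inv = np.linalg.inv(x.T @ v_inv @ x)
    beta = xtvx_inv @ x.T @ v_inv @ y
    return beta, xtvx_inv


def random_small_pedigree(rng: np.random.Generator, max_size: int = 8):
    """Random valid parent map of <= max_size members for property sweeps.

    Starts from 2-4 founders and adds children of random earlier pairs;
    returns the parents dict in topological (insertion) order.
    """
    n_founders = int(rng.integers(2, 5))
    parents: dict[str, tuple[str | None, str | None]] = {
        f"P{i}": (None, None) for i in range(n_founders)
    }
    size = int(rng.integers(n_founders, max_size + 1))
    while len(parents) < size:
        ids = list(parents)
        a, b = rng.choice(len(ids), size=2, replace=False)
        parents[f"P{len(parents)}"] = (ids[a], ids[b])
    return parents
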